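"""Independent brute-force oracles used by the test suite.

Each function here is deliberately simple (loops, closed forms) and shares
no code with the implementation paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations


def needleman_wunsch_identity(a: str, b: str, match=2, mismatch=-1, gap=-2) -> float:
    """Global alignment (linear gaps) identity over aligned columns."""
    m, n = len(a), len(b)
    score = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        score[i][0] = score[i - 1][0] + gap
    for j in range(1, n + 1):
        score[0][j] = score[0][j - 1] + gap
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            score[i][j] = max(score[i - 1][j - 1] + s,
                              score[i - 1][j] + gap,
                              score[i][j - 1] + gap)
    # traceback counting matches over aligned (substitution) columns
    i, j = m, n
    matches = aligned = 0
    while i > 0 and j > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if score[i][j] == score[i - 1][j - 1] + s:
            aligned += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif score[i][j] == score[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
    return matches / aligned if aligned else 0.0


def hd_pair_discordance(counts: list[int]) -> float:
    """Hd oracle: fraction of discordant unordered pairs, with the n/(n-1)
    correction folded in by construction (discordant pairs / C(n,2) equals
    n/(n-1) * (1 - sum p^2))."""
    n = sum(counts)
    total_pairs = n * (n - 1) // 2
    concordant = sum(c * (c - 1) // 2 for c in counts)
    return (total_pairs - concordant) / total_pairs


def pi_brute_force(seqs: list[str]) -> float:
    """Mean over unordered pairs of per-site differences, pairwise deletion,
    substitutions only (non-ACGT treated as missing)."""
    vals = []
    for a, b in combinations(seqs, 2):
        diffs = comp = 0
        for x, y in zip(a.upper(), b.upper()):
            if x in "ACGT" and y in "ACGT":
                comp += 1
                if x != y:
                    diffs += 1
        if comp:
            vals.append(diffs / comp)
    return sum(vals) / len(vals)


def tn93_from_counts(P1: float, P2: float, Q: float,
                     gA: float, gC: float, gG: float, gT: float) -> float:
    """Closed-form TN93 distance from substitution-class proportions and
    base frequencies."""
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    return (-k1 * math.log(1 - P1 / k1 - Q / (2 * gR))
            - k2 * math.log(1 - P2 / k2 - Q / (2 * gY))
            - k3 * math.log(1 - Q / (2 * gR * gY)))


def partitions(n: int, max_part: int | None = None):
    """All integer partitions of n (as count vectors)."""
    if n == 0:
        yield []
        return
    if max_part is None:
        max_part = n
    for k in range(min(n, max_part), 0, -1):
        for rest in partitions(n - k, k):
            yield [k] + rest


def random_additive_tree(n_leaves: int, rng):
    """Random unrooted tree with positive branch lengths; returns
    (labels, distance matrix as dict of leaf-pair -> path length,
    set of nontrivial splits as frozensets of labels)."""
    labels = [f"L{i}" for i in range(n_leaves)]
    # start from a star, repeatedly pair up nodes
    import itertools

    next_internal = [0]

    class N:
        def __init__(self, label=None):
            self.label = label
            self.children = []  # (child, length)

    nodes = [N(l) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = N()
        parent.children = [(nodes[i], float(rng.uniform(0.5, 3.0))),
                           (nodes[j], float(rng.uniform(0.5, 3.0)))]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = N()
    root.children = [(x, float(rng.uniform(0.5, 3.0))) for x in nodes]

    dists = {}
    splits = set()

    def leafset(node):
        if node.label:
            return {node.label}
        s = set()
        for c, _ in node.children:
            s |= leafset(c)
        return s

    def collect(node):
        tables = []
        for c, ln in node.children:
            t = {k: v + ln for k, v in collect(c).items()}
            tables.append(t)
            ls = frozenset(leafset(c))
            if 1 < len(ls) < n_leaves - 1:
                splits.add(ls)
        for ta, tb in itertools.combinations(tables, 2):
            for la, da in ta.items():
                for lb, db in tb.items():
                    dists[tuple(sorted((la, lb)))] = da + db
        merged = {}
        if node.label:
            merged[node.label] = 0.0
        for t in tables:
            merged.update(t)
        return merged

    collect(root)
    norm_splits = {s if "L0" not in s else frozenset(set(labels) - s)
                   for s in splits}
    return labels, dists, norm_splits
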