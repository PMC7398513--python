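"""Distance-based phylogeny: TN93 pairwise distances and neighbor-joining.

Distances are substitutions/site under the Tamura-Nei (1993) model with
base frequencies estimated from each sequence pair; sites with a gap or
ambiguity code in either sequence are excluded pairwise.  Trees come from
the classic Saitou-Nei neighbor-joining agglomeration with the
Studier-Keppler Q-criterion and are serialized as Newick.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Distance reported when the TN93 log argument saturates (<= 0).
SATURATION_CEILING = 5.0


# ---------------------------------------------------------------------------
# TN93

_ENC = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, -1) for c in seq.upper()], dtype=np.int8)


def tn93_distance(seq_a: str, seq_b: str, *,
                  ceiling: float = SATURATION_CEILING) -> float:
    """Tamura-Nei (TN93) maximum-likelihood distance between two aligned
    sequences, in substitutions/site.

    The two transition classes (A<->G and C<->T) are modeled separately
    from transversions; base frequencies are estimated from the pair over
    the pairwise-comparable sites.  A non-positive log argument
    (saturation) returns the configured ceiling with a warning.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    a = _encode(seq_a)
    b = _encode(seq_b)
    ok = (a >= 0) & (b >= 0)
    n = int(np.count_nonzero(ok))
    if n == 0:
        raise ValueError("no comparable sites")
    a, b = a[ok], b[ok]
    if np.array_equal(a, b):
        return 0.0
    # base frequencies from the pooled pair
    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    g = counts / counts.sum()
    gA, gC, gG, gT = g
    gR, gY = gA + gG, gC + gT
    diff = a != b
    purine = ((a == 0) | (a == 2)) & ((b == 0) | (b == 2))
    pyrimidine = ((a == 1) | (a == 3)) & ((b == 1) | (b == 3))
    P1 = float(np.count_nonzero(diff & purine)) / n        # A<->G transitions
    P2 = float(np.count_nonzero(diff & pyrimidine)) / n    # C<->T transitions
    Q = float(np.count_nonzero(diff & ~purine & ~pyrimidine)) / n
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            k1 = 2.0 * gA * gG / gR
            k2 = 2.0 * gC * gT / gY
            k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
            w1 = 1.0 - np.divide(P1, k1, out=np.zeros(1), where=k1 > 0)[0] - Q / (2.0 * gR)
            w2 = 1.0 - np.divide(P2, k2, out=np.zeros(1), where=k2 > 0)[0] - Q / (2.0 * gY)
            w3 = 1.0 - Q / (2.0 * gR * gY)
        # nan (degenerate frequencies) fails the > 0 check -> saturation path
        if not (w1 > 0.0 and w2 > 0.0 and w3 > 0.0):
            raise ValueError
        d = -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)
    except (ValueError, ZeroDivisionError):
        logger.warning("TN93 saturated; reporting ceiling %.1f subs/site", ceiling)
        return ceiling
    return min(d, ceiling)


def p_distance(seq_a: str, seq_b: str) -> float:
    a = _encode(seq_a)
    b = _encode(seq_b)
    ok = (a >= 0) & (b >= 0)
    if not np.any(ok):
        raise ValueError("no comparable sites")
    return float(np.count_nonzero((a != b) & ok)) / int(np.count_nonzero(ok))


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, finite

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("nonzero diagonal")
        object.__setattr__(self, "d", d)


def tn93_matrix(seqs: Mapping[str, str], *,
                ceiling: float = SATURATION_CEILING) -> DistanceMatrix:
    labels = tuple(seqs)
    k = len(labels)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = tn93_distance(seqs[labels[i]], seqs[labels[j]],
                                              ceiling=ceiling)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Trees

@dataclass
class TreeNode:
    """Node of an unrooted tree (represented with an arbitrary root whose
    children form the basal multifurcation)."""

    label: str = ""
    length: float = 0.0  # branch to parent
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between every unordered leaf pair (additivity checks)."""
        dists: dict[tuple[str, str], float] = {}

        def pairs(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            tables = []
            for c in node.children:
                t = {k: v + c.length for k, v in pairs(c).items()}
                tables.append(t)
            for i in range(len(tables)):
                for j in range(i + 1, len(tables)):
                    for la, da in tables[i].items():
                        for lb, db in tables[j].items():
                            key = (la, lb) if la < lb else (lb, la)
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for t in tables:
                merged.update(t)
            return merged

        pairs(self)
        return dists


def _quote_label(label: str) -> str:
    if any(c in label for c in "()[]{}:;, '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode, *, include_root_length: bool = False) -> str:
    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = _quote_label(node.label)
        else:
            body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.label:
                body += _quote_label(node.label)
        if top and not include_root_length:
            return body
        return f"{body}:{node.length:.10g}"

    return fmt(tree, True) + ";"


def write_newick(tree: TreeNode, path: str | Path,
                 annotations: Mapping[str, str] | None = None,
                 sep: str = "|") -> None:
    """Write Newick with full-precision branch lengths; optional per-leaf
    annotation strings are appended to leaf labels."""
    if annotations:
        for leaf in tree.leaves():
            extra = annotations.get(leaf.label)
            if extra:
                leaf.label = f"{leaf.label}{sep}{extra}"
    Path(path).write_text(to_newick(tree) + "\n")


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler Q-criterion.

    Deterministic: ties in Q select the lowest (i, j) active-index pair.
    Negative branch lengths are clamped to zero with the length transferred
    to the sibling branch.  The returned tree is unrooted, represented with
    a basal trifurcation (or a two-child root for two taxa).
    """
    labels = matrix.labels
    if len(labels) < 3:
        raise ValueError("neighbor joining requires >= 3 labels")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    d = matrix.d.astype(float).copy()
    active = list(range(len(labels)))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (r - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) pair on ties: scan in index order
        best = (np.inf, -1, -1)
        for i in range(r):
            for j in range(i + 1, r):
                if q[i, j] < best[0]:
                    best = (q[i, j], i, j)
        _, i, j = best
        ai, aj = active[i], active[j]
        dij = d[ai, aj]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2.0 * (r - 2))
        lj = dij - li
        if li < 0.0:  # clamp, transfer to sibling
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        nodes[ai].length = li
        nodes[aj].length = lj
        parent.children = [nodes[ai], nodes[aj]]
        # distances from the new node to the rest
        new_row = np.zeros(d.shape[0] + 1)
        for k_idx in active:
            if k_idx in (ai, aj):
                continue
            new_row[k_idx] = 0.5 * (d[ai, k_idx] + d[aj, k_idx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : -1] = new_row[:-1]
        d[: -1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [x for x in active if x not in (ai, aj)] + [len(nodes) - 1]
    # close the final three with the three-point formulas
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = TreeNode()
    for idx, ln in ((a, 0.5 * (dab + dac - dbc)),
                    (b, 0.5 * (dab + dbc - dac)),
                    (c, 0.5 * (dac + dbc - dab))):
        node = nodes[idx]
        node.length = max(ln, 0.0)
        root.children.append(node)
    return root


def build_tree(seqs: Mapping[str, str], *,
               ceiling: float = SATURATION_CEILING) -> TreeNode:
    """TN93 distances over unique haplotypes followed by neighbor joining."""
    return neighbor_joining(tn93_matrix(seqs, ceiling=ceiling))
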