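import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fawmarkers.phylo import (
    DistanceMatrix,
    SATURATION_CEILING,
    TreeNode,
    build_tree,
    neighbor_joining,
    p_distance,
    tn93_distance,
    tn93_matrix,
    to_newick,
    write_newick,
)

from oracles import random_additive_tree, tn93_from_counts


def mutate(seq, rng, n_transitions_ag, n_transitions_ct, n_transversions):
    """Apply counted substitution classes at distinct sites."""
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "C": "A", "G": "T", "T": "G"}
    s = list(seq)
    ag_sites = [i for i, c in enumerate(s) if c in "AG"]
    ct_sites = [i for i, c in enumerate(s) if c in "CT"]
    picked = set()
    def take(sites, n):
        out = []
        for i in sites:
            if len(out) == n:
                break
            if i not in picked:
                picked.add(i)
                out.append(i)
        return out
    for i in take(ag_sites, n_transitions_ag):
        s[i] = ts_map[s[i]]
    for i in take(ct_sites, n_transitions_ct):
        s[i] = ts_map[s[i]]
    for i in take([i for i in range(len(s)) if i not in picked], n_transversions):
        s[i] = tv_map[s[i]]
    return "".join(s)


class TestTn93:
    def test_identical_zero(self):
        assert tn93_distance("ACGTACGT" * 10, "ACGTACGT" * 10) == 0.0

    def test_equal_rates_limit_collapses_to_jukes_cantor(self, rng):
        # uniform base composition, the three substitution classes in
        # proportion 1:1:4 (each of the 6 unordered base pairs equally hit)
        n = 60000
        a = rng.choice(list("ACGT"), n)
        b = a.copy()
        idx = rng.choice(n, 6000, replace=False)
        for i in idx:
            b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
        sa, sb = "".join(a), "".join(b)
        p = p_distance(sa, sb)
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert tn93_distance(sa, sb) == pytest.approx(jc, rel=1e-3)

    def test_matches_closed_form_oracle_on_counted_classes(self):
        base = ("ACGT" * 300)
        other = mutate(base, None, 30, 24, 18)
        d = tn93_distance(base, other)
        n = len(base)
        counts = {c: base.count(c) + other.count(c) for c in "ACGT"}
        tot = sum(counts.values())
        expected = tn93_from_counts(
            30 / n, 24 / n, 18 / n,
            counts["A"] / tot, counts["C"] / tot, counts["G"] / tot, counts["T"] / tot,
        )
        assert d == pytest.approx(expected, rel=1e-12)

    def test_saturation_returns_ceiling(self):
        a = "A" * 30 + "C" * 30
        b = "C" * 30 + "A" * 30  # every site a transversion
        assert tn93_distance(a, b) == SATURATION_CEILING

    def test_gapped_and_ambiguous_sites_excluded_pairwise(self):
        d1 = tn93_distance("ACGTACGTAC-N", "ACGTACGTACGT")
        d2 = tn93_distance("ACGTACGTAC", "ACGTACGTAC")
        assert d1 == d2 == 0.0

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            tn93_distance("ACGT", "ACG")


@given(n_mut=st.integers(0, 40), seed=st.integers(0, 2**31))
@settings(max_examples=30, deadline=None)
def test_tn93_at_least_p_distance(n_mut, seed):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list("ACGT"), 400))
    b = list(a)
    for i in rng.choice(400, size=n_mut, replace=False):
        b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
    b = "".join(b)
    d = tn93_distance(a, b)
    p = p_distance(a, b)
    assert d >= p - 1e-12
    if p == 0:
        assert d == 0.0


class TestNeighborJoining:
    WORKED = DistanceMatrix(
        ("A", "B", "C", "D"),
        np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float),
    )

    def test_worked_four_taxon_example(self):
        # generated by tree ((A:1,B:2):1,(C:3,D:4)); path sums must
        # reproduce every input distance exactly
        tree = neighbor_joining(self.WORKED)
        dists = tree.leaf_distances()
        labels = self.WORKED.labels
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                b = labels[j]
                assert dists[(a, b)] == pytest.approx(self.WORKED.d[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        m = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = neighbor_joining(m)
        lengths = {c.label: c.length for c in tree.children}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    def test_random_additive_trees_recovered_exactly(self):
        """NJ reconstructs random additive matrices (n <= 12): topology via
        split sets and path sums to 1e-9."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 13))
            labels, dist_map, true_splits = random_additive_tree(n, rng)
            d = np.zeros((n, n))
            for i, a in enumerate(labels):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = dist_map[tuple(sorted((a, labels[j])))]
            tree = neighbor_joining(DistanceMatrix(tuple(labels), d))
            rec = tree.leaf_distances()
            for pair, v in dist_map.items():
                assert rec[pair] == pytest.approx(v, abs=1e-9), (seed, pair)
            assert _splits(tree, set(labels)) == true_splits, seed

    def test_ultrametric_matrix_matches_upgma_topology(self):
        # oracle: brute force over the 3 possible unrooted 4-taxon
        # topologies by additive fit
        labels = ("A", "B", "C", "D")
        d = np.array([[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        splits = _splits(tree, set(labels))
        assert frozenset({"C", "D"}) in splits or frozenset({"A", "B"}) in splits

    def test_leaf_set_preserved(self):
        tree = neighbor_joining(self.WORKED)
        assert {l.label for l in tree.leaves()} == set(self.WORKED.labels)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B", "C"), d)

    def test_non_finite_rejected(self):
        d = np.array([[0, np.inf, 2], [np.inf, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="finite"):
            DistanceMatrix(("A", "B", "C"), d)

    def test_label_order_invariance_up_to_isomorphism(self):
        labels = self.WORKED.labels
        perm = (2, 0, 3, 1)
        d2 = self.WORKED.d[np.ix_(perm, perm)]
        t1 = neighbor_joining(self.WORKED)
        t2 = neighbor_joining(DistanceMatrix(tuple(labels[i] for i in perm), d2))
        assert _splits(t1, set(labels)) == _splits(t2, set(labels))
        d1, dd2 = t1.leaf_distances(), t2.leaf_distances()
        for pair in d1:
            assert d1[pair] == pytest.approx(dd2[pair], abs=1e-9)


def _splits(tree: TreeNode, all_labels: set[str]) -> set[frozenset]:
    splits = set()

    def leafset(node):
        if node.is_leaf:
            return {node.label}
        s = set()
        for c in node.children:
            s |= leafset(c)
        return s

    def walk(node):
        for c in node.children:
            ls = leafset(c)
            if 1 < len(ls) < len(all_labels) - 1:
                # normalize: keep the side not containing the first label
                first = sorted(all_labels)[0]
                norm = frozenset(all_labels - ls) if first in ls else frozenset(ls)
                splits.add(norm)
            walk(c)

    walk(tree)
    return splits


class TestNewick:
    def test_three_leaf_form(self):
        m = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        s = to_newick(neighbor_joining(m))
        assert s.startswith("(") and s.endswith(");")
        assert all(x in s for x in ("A:", "B:", "C:"))

    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        tree = neighbor_joining(TestNeighborJoining.WORKED)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = back.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in back.taxon_namespace}
        orig = tree.leaf_distances()
        for (a, b), v in orig.items():
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(v, abs=1e-10)

    def test_labels_with_parentheses_quoted(self, tmp_path):
        tree = TreeNode(children=[TreeNode("ha(p)1", 1.0), TreeNode("x;y", 2.0),
                                  TreeNode("ok", 3.0)])
        path = tmp_path / "q.nwk"
        write_newick(tree, path)
        text = path.read_text()
        assert "'ha(p)1'" in text and "'x;y'" in text
        back = dendropy.Tree.get(path=str(path), schema="newick")
        labels = {t.label for t in back.taxon_namespace}
        assert "ha(p)1" in labels and "x;y" in labels

    def test_annotations_appended(self, tmp_path):
        tree = TreeNode(children=[TreeNode("a", 1.0), TreeNode("b", 1.0),
                                  TreeNode("c", 1.0)])
        path = tmp_path / "a.nwk"
        write_newick(tree, path, annotations={"a": "CS;Ecuador"})
        assert "'a|CS;Ecuador'" in path.read_text()


def test_build_tree_from_sequences(rng):
    base = "".join(rng.choice(list("ACGT"), 200))
    seqs = {"h1": base}
    for i in range(2, 6):
        s = list(base)
        for j in rng.choice(200, size=5 * i, replace=False):
            s[j] = rng.choice([x for x in "ACGT" if x != base[j]])
        seqs[f"h{i}"] = "".join(s)
    tree = build_tree(seqs)
    assert {l.label for l in tree.leaves()} == set(seqs)
    assert all(c.length >= 0 for c in tree.children)
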