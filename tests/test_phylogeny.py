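"""Distance phylogenetics: JC distances, UPGMA/NJ, bootstrap, Newick."""

import math

import numpy as np
import pytest

from estuarybin.phylogeny import (
    MARKER_GENE_SET,
    ConcatenatedAlignment,
    TreeNode,
    bipartitions,
    bootstrap,
    concatenate,
    distance_matrix,
    filter_taxa,
    jc_distance,
    neighbor_joining,
    upgma,
    write_newick,
)


# ---------------------------------------------------------------------------
# helpers


def leaf_depths(node, acc=0.0, out=None):
    out = {} if out is None else out
    if node.is_leaf():
        out[node.name] = acc + node.length
    for ch in node.children:
        leaf_depths(ch, acc + (0.0 if node.length is None else node.length)
                    if node.name is None else acc, out)
    return out


def tree_distances(node):
    """Leaf-to-leaf path lengths of a tree (brute force)."""
    def collect(n):
        if n.is_leaf():
            return {n.name: n.length}
        merged = {}
        out = {}
        for ch in n.children:
            sub = collect(ch)
            for other_leaf, dist_other in merged.items():
                for leaf, dist in sub.items():
                    out[frozenset((other_leaf, leaf))] = dist + dist_other
            merged.update(sub)
        collect.paths.update(out)
        return {k: v + n.length for k, v in merged.items()}

    collect.paths = {}
    collect(node)
    return collect.paths


def random_additive_tree(n_taxa, rng):
    """A random binary tree with positive branch lengths and its exact
    additive distance matrix."""
    nodes = [TreeNode(name=chr(65 + i), length=float(rng.uniform(0.2, 1.5)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = TreeNode(length=float(rng.uniform(0.2, 1.5)),
                          children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = TreeNode(children=nodes)
    root.length = 0.0
    paths = tree_distances(root)
    taxa = sorted(root.leaves())
    D = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            D[a, b] = D[b, a] = paths[frozenset((taxa[a], taxa[b]))]
    return root, D, taxa


# ---------------------------------------------------------------------------


class TestFilterTaxa:
    def test_half_presence_boundary(self):
        presence = {
            "keep8": {g: i < 8 for i, g in enumerate(MARKER_GENE_SET)},
            "drop7": {g: i < 7 for i, g in enumerate(MARKER_GENE_SET)},
            "full": {g: True for g in MARKER_GENE_SET},
        }
        assert set(filter_taxa(presence)) == {"keep8", "full"}

    def test_all_complete_identity(self):
        presence = {f"t{i}": {g: True for g in MARKER_GENE_SET} for i in range(5)}
        assert set(filter_taxa(presence)) == set(presence)


class TestConcatenate:
    def test_partitions_and_gap_fill(self):
        aln = concatenate(
            {"rpL2": {"A": "MKV" * 3 + "L", "B": "MKI" * 3 + "L"},
             "rpL3": {"A": "W" * 20}},
            gene_set=("rpL2", "rpL3"),
        )
        assert aln.n_columns == 30
        assert aln.partitions == [("rpL2", 0, 10), ("rpL3", 10, 30)]
        assert aln.rows["B"][10:] == "-" * 20
        for t in aln.taxa:
            assert len(aln.rows[t]) == 30

    def test_ragged_gene_rejected(self):
        with pytest.raises(ValueError, match="rpL2"):
            concatenate({"rpL2": {"A": "MK", "B": "MKV"}}, gene_set=("rpL2",))


class TestJCDistance:
    def test_identical_rows_zero(self):
        assert jc_distance("MKVLW", "MKVLW") == 0.0

    def test_closed_form_p019(self):
        row_a = "A" * 81 + "C" * 19
        row_b = "A" * 100
        assert jc_distance(row_a, row_b, n_states=20) == pytest.approx(
            0.21199, abs=1e-5
        )

    def test_monotone_in_p(self):
        prev = -1.0
        for mism in range(0, 90, 10):
            d = jc_distance("A" * (100 - mism) + "C" * mism, "A" * 100)
            assert d > prev
            prev = d

    def test_gap_columns_excluded(self):
        assert jc_distance("MK-V", "MKW-") == 0.0  # only 2 shared, both equal

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ValueError):
            jc_distance("M-", "-M")

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            jc_distance("ACDEFGHIKLMNPQRSTVWY", "CDEFGHIKLMNPQRSTVWYA")


class TestUPGMA:
    def test_three_taxon_hand_example(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        t = upgma(d, ["A", "B", "C"])
        assert write_newick(t) == "((A:1,B:1):1,C:2);"
        depths = {k: v for k, v in _root_depths(t).items()}
        assert all(v == pytest.approx(2.0) for v in depths.values())

    def test_two_taxa(self):
        t = upgma(np.array([[0, 3.0], [3.0, 0]]), ["A", "B"])
        assert write_newick(t) == "(A:1.5,B:1.5);"

    def test_ultrametric_root_leaf_depths_equal(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            d = _random_matrix(6, rng)
            t = upgma(d, [f"t{i}" for i in range(6)])
            depths = _root_depths(t)
            vals = list(depths.values())
            assert max(vals) - min(vals) < 1e-9  # UPGMA trees are ultrametric

    def test_scipy_average_linkage_oracle(self):
        """Cophenetic distances agree with scipy's average-linkage
        (independent UPGMA implementation) on random matrices."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        for _ in range(25):
            n = 5
            d = _random_matrix(n, rng)
            taxa = [f"t{i}" for i in range(n)]
            mine = tree_distances(upgma(d, taxa))
            condensed = squareform(d)
            coph = squareform(cophenet(linkage(condensed, method="average")))
            for a in range(n):
                for b in range(a + 1, n):
                    assert mine[frozenset((taxa[a], taxa[b]))] == pytest.approx(
                        coph[a, b], abs=1e-9
                    )

    def test_nan_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError):
            upgma(d, ["A", "B"])


class TestNJ:
    def test_additive_recovery_4_to_8_taxa(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            true_tree, D, taxa = random_additive_tree(n, rng)
            est = neighbor_joining(D, taxa)
            assert bipartitions(est) == bipartitions(true_tree), trial
            # branch lengths: compare all leaf-leaf path lengths
            est_paths = tree_distances(est)
            for a in range(n):
                for b in range(a + 1, n):
                    assert est_paths[frozenset((taxa[a], taxa[b]))] == pytest.approx(
                        D[a, b], abs=1e-9
                    )

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float)
        t = neighbor_joining(d, ["A", "B", "C"])
        by_name = {ch.name: ch.length for ch in t.children}
        assert by_name["A"] == pytest.approx((5 + 9 - 8) / 2)
        assert by_name["B"] == pytest.approx((5 + 8 - 9) / 2)
        assert by_name["C"] == pytest.approx((9 + 8 - 5) / 2)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(6)
        _, D, taxa = random_additive_tree(6, rng)
        t1 = neighbor_joining(D, taxa)
        perm = rng.permutation(6)
        Dp = D[np.ix_(perm, perm)]
        t2 = neighbor_joining(Dp, [taxa[i] for i in perm])
        assert bipartitions(t1) == bipartitions(t2)


class TestBootstrap:
    def _clean_alignment(self, n_cols=500):
        """Zero-homoplasy ultrametric 8-taxon alignment: each edge of the
        balanced tree owns a block of columns where exactly its descendants
        carry a derived state."""
        taxa = [f"t{i}" for i in range(8)]
        clades = [
            {0, 1}, {2, 3}, {4, 5}, {6, 7},
            {0, 1, 2, 3}, {4, 5, 6, 7},
        ]
        per_edge = n_cols // len(clades)
        cols = []
        for ci, clade in enumerate(clades):
            for _ in range(per_edge):
                cols.append(["W" if i in clade else "A" for i in range(8)])
        # pad with invariant columns
        while len(cols) < n_cols:
            cols.append(["A"] * 8)
        rows = {t: "".join(c[i] for c in cols) for i, t in enumerate(taxa)}
        return ConcatenatedAlignment(
            taxa=taxa, rows=rows, partitions=[("synthetic", 0, n_cols)]
        ), clades, taxa

    def test_clean_alignment_full_support(self):
        aln, clades, taxa = self._clean_alignment(500)
        tree = bootstrap(aln, upgma, n_replicates=100, seed=1)
        supports = _collect_supports(tree)
        expected_clades = {frozenset(taxa[i] for i in c) for c in clades}
        found = {frozenset(k): v for k, v in supports.items()}
        for clade in expected_clades:
            side = min(clade, frozenset(taxa) - clade,
                       key=lambda s: (len(s), tuple(sorted(s))))
            assert found.get(side) == 100, clade

    def test_zero_replicates_no_supports(self):
        aln, _, _ = self._clean_alignment(100)
        tree = bootstrap(aln, upgma, n_replicates=0, seed=0)
        assert _collect_supports(tree) == {}

    def test_supports_in_range(self):
        rng = np.random.default_rng(9)
        taxa = [f"t{i}" for i in range(6)]
        rows = {
            t: "".join(rng.choice(list("ACDE"), 60)) for t in taxa
        }
        aln = ConcatenatedAlignment(taxa=taxa, rows=rows,
                                    partitions=[("x", 0, 60)])
        tree = bootstrap(aln, upgma, n_replicates=50, seed=2)
        for v in _collect_supports(tree).values():
            assert 0 <= v <= 100

    def test_support_grows_with_columns(self):
        means = []
        for n_cols in (48, 198, 498):
            aln, clades, taxa = self._clean_alignment(n_cols)
            tree = bootstrap(aln, upgma, n_replicates=50, seed=3)
            sup = _collect_supports(tree)
            means.append(np.mean(list(sup.values())))
        assert means[0] <= means[1] + 1e-9 <= means[2] + 2e-9


class TestNewick:
    def test_supported_internal_label(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        t = upgma(d, ["A", "B", "C"])
        for node in t.children:
            if not node.is_leaf():
                node.support = 100
        assert write_newick(t) == "((A:1,B:1)100:1,C:2);"

    def test_single_leaf(self):
        assert write_newick(TreeNode(name="A")) == "A:0;"

    def test_metacharacter_names_quoted(self):
        t = TreeNode(children=[TreeNode(name="a b", length=1.0),
                               TreeNode(name="c", length=1.0)])
        assert write_newick(t) == "('a b':1,c:1);"

    def test_roundtrip_via_dendropy(self):
        import dendropy

        rng = np.random.default_rng(10)
        _, D, taxa = random_additive_tree(6, rng)
        aln_tree = neighbor_joining(D, taxa)
        text = write_newick(aln_tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        labels = {
            frozenset(l.taxon.label for l in e.head_node.leaf_iter())
            for e in parsed.preorder_edge_iter()
            if e.head_node.parent_node is not None
        }
        # every internal bipartition of my tree survives serialization
        for side in bipartitions(aln_tree):
            full = frozenset(taxa)
            assert side in labels or (full - side) in labels


# ---------------------------------------------------------------------------


def _root_depths(tree):
    out = {}

    def walk(node, acc):
        if node.is_leaf():
            out[node.name] = acc + node.length
            return
        for ch in node.children:
            walk(ch, acc + (node.length if node is not tree else 0.0))

    walk(tree, 0.0)
    return out


def _collect_supports(tree):
    out = {}

    def walk(node, leaves_out):
        if node.is_leaf():
            return {node.name}
        below = set()
        for ch in node.children:
            below |= walk(ch, leaves_out)
        if node.support is not None:
            all_leaves = frozenset(tree.leaves())
            side = min(frozenset(below), all_leaves - below,
                       key=lambda s: (len(s), tuple(sorted(s))))
            out[side] = node.support
        return below

    walk(tree, out)
    return out


def _random_matrix(n, rng):
    x = rng.uniform(0.5, 3.0, size=(n, n))
    d = (x + x.T) / 2
    np.fill_diagonal(d, 0.0)
    return d
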