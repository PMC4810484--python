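"""MLSA phylogenetics: distances, NJ, bootstrap, RF congruence."""

import itertools
import math

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from steromine.errors import AnalysisError, InputError
from steromine.evolution import EvolutionModel, evolve_along_tree, random_protein
from steromine.phylo import (
    bipartitions,
    bootstrap_support,
    build_supermatrix,
    distance_matrix,
    extract_markers,
    nj_tree,
    protein_distance,
    rf_distance,
)


def all_binary_topologies(leaves):
    """Enumerate every unrooted binary topology by sequential leaf addition."""
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    trees = [TreeNode.read([f"({leaves[0]},{leaves[1]},{leaves[2]});"])]
    for leaf in leaves[3:]:
        nxt = []
        for tree in trees:
            edges = [n for n in tree.traverse(include_self=False)]
            for i in range(len(edges)):
                t2 = tree.copy()
                e2 = [n for n in t2.traverse(include_self=False)][i]
                parent = e2.parent
                new_internal = TreeNode()
                parent.remove(e2)
                new_internal.append(e2)
                new_internal.append(TreeNode(name=leaf))
                parent.append(new_internal)
                nxt.append(t2)
        trees = nxt
    return trees


def additive_matrix(tree, rng):
    for node in tree.traverse(include_self=False):
        node.length = float(rng.uniform(0.2, 1.0))
    names = sorted(t.name for t in tree.tips())
    n = len(names)
    d = np.zeros((n, n))
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.find(a).distance(tree.find(names[j]))
    return DistanceMatrix(d, ids=names)


class TestProteinDistance:
    def test_identical_rows_zero(self):
        assert protein_distance("ACDEF", "ACDEF") == 0.0

    def test_half_different_closed_form(self):
        assert protein_distance("AAAA", "AACC") == pytest.approx(-math.log(0.5))

    def test_matches_hand_count_with_gaps(self):
        rng = np.random.default_rng(4)
        letters = list("ACDE-")
        for _ in range(30):
            n = int(rng.integers(2, 31))
            a = "".join(rng.choice(letters, n))
            b = "".join(rng.choice(letters, n))
            shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not shared:
                with pytest.raises(InputError):
                    protein_distance(a, b)
                continue
            p = sum(x != y for x, y in shared) / len(shared)
            if p >= 1.0:
                with pytest.raises(AnalysisError):
                    protein_distance(a, b)
            else:
                assert protein_distance(a, b) == pytest.approx(-math.log(1 - p))

    def test_saturation_raises(self):
        with pytest.raises(AnalysisError):
            protein_distance("AAAA", "CCCC")


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float), ids=["A", "B", "C"]
        )
        tree = nj_tree(d)
        # three-point formulas: a = (dAB + dAC - dBC)/2, etc.
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(2.0)
        assert tree.find("C").length == pytest.approx(3.0)

    def test_additive_five_taxon_recovery(self):
        rng = np.random.default_rng(7)
        true = TreeNode.read(["((A,B),(C,D),E);"])
        dm = additive_matrix(true, rng)
        assert rf_distance(nj_tree(dm), true) == 0

    def test_consistency_on_all_topologies_up_to_six_leaves(self):
        """NJ recovers the generating topology (RF = 0) from additive
        matrices for every binary topology with <= 6 leaves."""
        rng = np.random.default_rng(11)
        for n in (4, 5, 6):
            leaves = [f"L{i}" for i in range(n)]
            for tree in all_binary_topologies(leaves):
                dm = additive_matrix(tree, rng)
                assert rf_distance(nj_tree(dm), tree) == 0

    def test_nonsymmetric_matrix_rejected(self):
        with pytest.raises(InputError):
            nj_tree((np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]]), ["a", "b", "c"]))

    def test_equidistant_taxa_have_zero_internal_branches(self):
        d = np.ones((4, 4)) - np.eye(4)
        tree = nj_tree(DistanceMatrix(d, ids=list("ABCD")))
        for node in tree.non_tips(include_self=False):
            assert node.length == pytest.approx(0.0, abs=1e-12)


class TestRfDistance:
    def test_tree_vs_itself_zero(self):
        t = TreeNode.read(["((A,B),(C,D),E);"])
        assert rf_distance(t, t.copy()) == 0

    def test_two_distinct_quartets(self):
        a = TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])
        b = TreeNode.read(["((A:1,C:1):1,(B:1,D:1):1);"])
        assert rf_distance(a, b) == 2

    def test_matches_dendropy_on_random_pairs(self):
        """Independent oracle: dendropy's bipartition symmetric difference."""
        import dendropy

        rng = np.random.default_rng(21)
        for n in (4, 5, 6, 7):
            leaves = [f"T{i}" for i in range(n)]
            topos = all_binary_topologies(leaves)
            for _ in range(6):
                ta = topos[int(rng.integers(len(topos)))].copy()
                tb = topos[int(rng.integers(len(topos)))].copy()
                for t in (ta, tb):
                    for node in t.traverse(include_self=False):
                        node.length = 1.0
                tns = dendropy.TaxonNamespace()
                da = dendropy.Tree.get(data=str(ta), schema="newick", taxon_namespace=tns)
                db = dendropy.Tree.get(data=str(tb), schema="newick", taxon_namespace=tns)
                expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
                assert rf_distance(ta, tb) == expected

    def test_too_few_shared_leaves_rejected(self):
        a = TreeNode.read(["((A,B),(C,D),E);"])
        b = TreeNode.read(["((A,X),(Y,Z),B);"])
        with pytest.raises(InputError):
            rf_distance(a, b)


@pytest.fixture(scope="module")
def marker_sets():
    rng = np.random.default_rng(2)
    roots = {m: random_protein(120, rng) for m in ("m1", "m2", "m3")}
    sp = TreeNode.read(
        ["(((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3):0.2,(E:0.4,F:0.4):0.3);"]
    )
    leaf = evolve_along_tree(roots, sp, EvolutionModel(seed=4))
    return leaf, sp


class TestSupermatrix:

    def test_block_coordinates_partition_columns(self, marker_sets):
        leaf, _ = marker_sets
        sm = build_supermatrix(leaf, ("m1", "m2", "m3"))
        assert sm.block_coords[0][1] == 0
        for (m1, s1, e1), (m2, s2, e2) in zip(sm.block_coords, sm.block_coords[1:]):
            assert e1 == s2
        assert sm.block_coords[-1][2] == sm.n_columns

    def test_identical_sequences_have_no_variable_columns(self):
        seqs = {t: {"m": "ACDEFGHIKL"} for t in ("A", "B", "C")}
        sm = build_supermatrix(seqs, ("m",))
        assert len({sm.rows[t] for t in sm.taxa}) == 1

    def test_taxon_order_invariance(self, marker_sets):
        leaf, _ = marker_sets
        sm1 = build_supermatrix(leaf, ("m1", "m2", "m3"))
        shuffled = dict(reversed(list(leaf.items())))
        sm2 = build_supermatrix(shuffled, ("m1", "m2", "m3"))
        assert sm1.rows == sm2.rows

    def test_extract_markers_drop_report(self):
        sets = {
            "full": {"m1": "ACD", "m2": "ACD"},
            "partial": {"m1": "ACD", "m2": None},
        }
        kept, dropped = extract_markers(sets, ("m1", "m2"))
        assert list(kept) == ["full"]
        assert dropped == ["partial"]
        with pytest.raises(AnalysisError):
            extract_markers({"x": {"m1": None}}, ("m1",))


@pytest.fixture(scope="module")
def structured():
    rng = np.random.default_rng(2)
    roots = {f"m{i}": random_protein(150, rng) for i in range(4)}
    sp = TreeNode.read(
        ["(((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3):0.2,(E:0.4,F:0.4):0.3);"]
    )
    leaf = evolve_along_tree(roots, sp, EvolutionModel(seed=4))
    return build_supermatrix(leaf, tuple(sorted(roots))), sp


class TestBootstrap:

    def test_true_bipartitions_strongly_supported(self, structured):
        """Long internal branches: every true bipartition >= 95% support."""
        sm, sp = structured
        tree, support = bootstrap_support(sm, n_replicates=100, seed=3)
        assert rf_distance(tree, sp) == 0
        assert support and all(v >= 95.0 for v in support.values())

    def test_single_replicate_supports_are_binary(self, structured):
        sm, _ = structured
        _, support = bootstrap_support(sm, n_replicates=1, seed=8)
        assert set(support.values()) <= {0.0, 100.0}

    def test_deterministic_under_seed(self, structured):
        sm, _ = structured
        _, s1 = bootstrap_support(sm, n_replicates=25, seed=5)
        _, s2 = bootstrap_support(sm, n_replicates=25, seed=5)
        assert s1 == s2

    def test_zero_variable_columns_supports_bounded(self):
        seqs = {t: {"m": "ACDEFGHIKLMNPQ"} for t in ("A", "B", "C", "D")}
        sm = build_supermatrix(seqs, ("m",))
        _, support = bootstrap_support(sm, n_replicates=10, seed=1)
        assert all(0.0 <= v <= 100.0 for v in support.values())
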