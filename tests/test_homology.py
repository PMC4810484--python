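"""Similarity-graph binning and greedy incremental clustering."""

import numpy as np
import pytest

from steromine.errors import InputError
from steromine.evolution import EvolutionModel, evolve_sequence, random_protein
from steromine.homology import (
    HomologyGraph,
    build_graph,
    cluster_identity,
    connected_components,
    greedy_cluster,
    retain_seeded,
)


def reference_greedy(proteins, min_identity, scheme=None):
    """Independent step-by-step re-implementation used as the oracle (no
    prefilter; plain scan in creation order)."""
    order = sorted(proteins, key=lambda i: (-len(proteins[i]), i))
    clusters = []
    for pid in order:
        for cluster in clusters:
            if cluster_identity(proteins[pid], proteins[cluster[0]], scheme) >= min_identity:
                cluster.append(pid)
                break
        else:
            clusters.append([pid])
    return clusters


@pytest.fixture(scope="module")
def families():
    """Three unrelated families, internally diverged to ~60% identity."""
    rng = np.random.default_rng(3)
    fams = {}
    for f in range(3):
        anc = random_protein(160, rng)
        for i in range(3):
            fams[f"f{f}_m{i}"] = (
                anc if i == 0 else evolve_sequence(anc, 0.6, EvolutionModel(seed=10 * f + i))
            )
    return fams


class TestBuildGraph:
    def test_identical_pair_single_edge(self):
        seq = random_protein(120, np.random.default_rng(0))
        g = build_graph({"a": seq, "b": seq})
        assert g.edges() == [("a", "b", 1.0, g.edges()[0][3])]
        assert g.edges()[0][3] <= 1e-30

    def test_families_form_separate_components(self, families):
        g = build_graph(families)
        comps = connected_components(g)
        assert len(comps) == 3
        for comp in comps:
            prefixes = {m.split("_")[0] for m in comp}
            assert len(prefixes) == 1

    def test_unreachable_identity_threshold_gives_empty_graph(self, families):
        g = build_graph(families, min_identity=1.01)
        assert g.edges() == []

    def test_threshold_monotonicity(self, families):
        n_loose = len(connected_components(build_graph(families, min_identity=0.30)))
        n_tight = len(connected_components(build_graph(families, min_identity=0.8)))
        assert n_tight >= n_loose


class TestConnectedComponents:
    def test_edgeless_graph_gives_singletons(self):
        import networkx as nx

        g = HomologyGraph(nx.empty_graph(["a", "b", "c", "d", "e"]), 0.3, 1e-30)
        comps = connected_components(g)
        assert sorted(map(len, comps)) == [1, 1, 1, 1, 1]

    def test_path_graph_single_component(self):
        import networkx as nx

        gg = nx.Graph([("a", "b"), ("b", "c")])
        assert connected_components(HomologyGraph(gg, 0.3, 1e-30)) == [{"a", "b", "c"}]

    def test_random_graphs_match_transitive_closure(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            nodes = [f"n{i}" for i in range(n)]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        g.add_edge(nodes[i], nodes[j])
            comps = connected_components(HomologyGraph(g, 0.3, 1e-30))
            # oracle: boolean reachability via matrix powers
            adj = np.eye(n, dtype=bool)
            for a, b in g.edges:
                ia, ib = nodes.index(a), nodes.index(b)
                adj[ia, ib] = adj[ib, ia] = True
            reach = adj.copy()
            for _ in range(n):
                reach = reach @ adj | reach
            oracle = set()
            for i in range(n):
                oracle.add(frozenset(nodes[j] for j in range(n) if reach[i, j]))
            assert {frozenset(c) for c in comps} == oracle


class TestGreedyCluster:
    def test_identical_pair_one_cluster(self):
        seq = random_protein(100, np.random.default_rng(1))
        out = greedy_cluster({"a": seq, "b": seq})
        assert out.clusters == [["a", "b"]]

    def test_families_reproduce_labels(self, families):
        """At the 50% threshold, families diverged to ~60% internally and
        unrelated between stay as 1-3 subclusters per family."""
        out = greedy_cluster(families)
        for cluster in out.clusters:
            assert len({m.split("_")[0] for m in cluster}) == 1
        assert 3 <= len(out.clusters) <= 9

    def test_matches_reference_implementation_on_corpus(self):
        """30 seeded inputs of <= 6 proteins: greedy output equals the
        independent step-by-step oracle."""
        rng = np.random.default_rng(9)
        for case in range(30):
            n = int(rng.integers(2, 7))
            proteins = {}
            anc = random_protein(int(rng.integers(40, 90)), rng)
            for i in range(n):
                if rng.random() < 0.5:
                    proteins[f"p{i}"] = evolve_sequence(
                        anc, float(rng.uniform(0.35, 0.95)), EvolutionModel(seed=case * 10 + i)
                    )
                else:
                    proteins[f"p{i}"] = random_protein(int(rng.integers(40, 90)), rng)
            out = greedy_cluster(proteins)
            assert out.clusters == reference_greedy(proteins, 0.5)

    def test_partition_and_representative_identity(self, families):
        out = greedy_cluster(families)
        members = [m for c in out.clusters for m in c]
        assert sorted(members) == sorted(families)  # partition
        for cluster in out.clusters:
            rep = families[cluster[0]]
            for m in cluster[1:]:
                assert cluster_identity(families[m], rep) >= out.min_identity

    def test_word_size_validation(self, families):
        with pytest.raises(InputError):
            greedy_cluster(families, word_size=0)


class TestRetainSeeded:
    def _clusters(self):
        from steromine.homology import SubclusterSet

        return SubclusterSet(
            clusters=[["a", "b"], ["c"], ["d", "e"], ["f"], ["g"]], min_identity=0.5
        )

    def test_keeps_only_seeded_clusters(self):
        out = retain_seeded(self._clusters(), ["b", "f"])
        assert out.clusters == [["a", "b"], ["f"]]

    def test_all_seeded_is_identity(self):
        out = retain_seeded(self._clusters(), ["a", "c", "d", "f", "g"])
        assert out.clusters == self._clusters().clusters

    def test_no_seed_hits_gives_empty(self):
        # seed must exist among members; use one that matches nothing else
        out = retain_seeded(self._clusters(), ["g"])
        assert out.clusters == [["g"]]

    def test_unknown_seed_rejected(self):
        with pytest.raises(InputError):
            retain_seeded(self._clusters(), ["zz"])
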