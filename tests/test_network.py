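"""Median-joining network: weights, MSN/MST containment, medians, exports."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from ylineage import (
    build_mj_network,
    compute_str_weights,
    export_network,
    minimum_spanning_network,
)
from ylineage.network import read_graphml_network, weighted_steps
from ylineage.profiles import STRProfile

from conftest import make_profile


def profiles_from_vectors(vectors, loci=("L1", "L2", "L3"), pops=None):
    return [
        make_profile(
            f"s{i}", dict(zip(loci, v)),
            population=(pops[i] if pops else "pop1"),
        )
        for i, v in enumerate(vectors)
    ]


class TestWeights:
    def test_equal_variance_gives_equal_weights(self):
        profs = profiles_from_vectors([(10, 10, 10), (11, 11, 11)])
        w = compute_str_weights(profs)
        assert len(set(w.values())) == 1

    def test_weight_inverse_to_variance(self, three_locus_profiles):
        """Hand computation: variances DYS19=0.75, DYS390=0.1875, DYS391=0.25
        -> weights 1, 4, 3 (scaled so the most variable locus gets 1)."""
        w = compute_str_weights(three_locus_profiles)
        assert w == {"DYS19": 1, "DYS390": 4, "DYS391": 3}

    def test_four_fold_variance_ratio(self):
        # L1 alleles 10,14 (var 4); L2 alleles 10,12 (var 1)
        profs = profiles_from_vectors([(10, 10), (14, 12)], loci=("L1", "L2"))
        w = compute_str_weights(profs)
        assert w["L2"] == 4 * w["L1"]

    def test_zero_variance_gets_maximum_weight(self):
        profs = profiles_from_vectors([(10, 10), (11, 10)], loci=("L1", "L2"))
        assert compute_str_weights(profs)["L2"] == 99

    def test_uniform_scheme(self, three_locus_profiles):
        assert set(compute_str_weights(three_locus_profiles, "uniform").values()) == {1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_str_weights([])

    def test_excluded_loci_never_weighted(self):
        profs = [
            make_profile("a", {"DYS19": 13, "DYS385a": 11}),
            make_profile("b", {"DYS19": 14, "DYS385a": 17}),
        ]
        assert set(compute_str_weights(profs)) == {"DYS19"}


class TestBuildNetwork:
    def test_identical_profiles_collapse_to_single_node(self):
        profs = profiles_from_vectors([(10, 10, 10)] * 5)
        net = build_mj_network(profs)
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0
        node = net.graph.nodes[0]
        assert node["frequency"] == 5 and node["kind"] == "observed"

    def test_single_step_pair(self):
        profs = profiles_from_vectors([(10, 10, 10), (10, 11, 10)])
        weights = {"L1": 2, "L2": 5, "L3": 2}
        net = build_mj_network(profs, weights=weights)
        assert net.graph.number_of_nodes() == 2
        ((u, v, d),) = net.graph.edges(data=True)
        assert d["weight"] == 5
        assert d["steps"] == {"L2": 1}

    def test_median_vector_shortens_the_network(self):
        """Three haplotypes whose coordinate-wise median is a fourth point:
        the MJ network adds exactly that Steiner node and beats every
        observed-only spanning tree (enumeration over the 3 trees)."""
        vecs = [(10, 10, 10), (11, 11, 10), (11, 10, 11)]
        profs = profiles_from_vectors(vecs)
        net = build_mj_network(profs)
        medians = [net.haplotype_of(n) for n in net.median_nodes]
        assert medians == [(11, 10, 10)]
        wvec = np.ones(3, dtype=np.int64)
        pairwise = {
            frozenset((i, j)): weighted_steps(vecs[i], vecs[j], wvec)
            for i, j in itertools.combinations(range(3), 2)
        }
        best_tree = min(
            sum(pairwise[frozenset(e)] for e in tree)
            for tree in itertools.combinations(itertools.combinations(range(3), 2), 2)
            if len({n for e in tree for n in e}) == 3
        )
        assert net.total_length() < best_tree

    def test_network_contains_brute_force_mst(self):
        """The epsilon=0 MSN is the union of all MSTs, so it must contain
        every edge of an independently computed MST; the MJ network's
        Steiner cost never exceeds the observed-only MST cost."""
        rng = np.random.default_rng(0)
        for trial in range(8):
            n = int(rng.integers(3, 9))
            vecs = [tuple(int(x) for x in rng.integers(9, 14, size=4)) for _ in range(n)]
            vecs = list(dict.fromkeys(vecs))
            wvec = np.ones(4, dtype=np.int64)
            # oracle MST via networkx on the complete weighted graph
            g = nx.Graph()
            for i, j in itertools.combinations(range(len(vecs)), 2):
                g.add_edge(i, j, weight=weighted_steps(vecs[i], vecs[j], wvec))
            mst = nx.minimum_spanning_tree(g)
            mst_cost = mst.size(weight="weight")
            msn = set(minimum_spanning_network(vecs, wvec, epsilon=0.0))
            for u, v in mst.edges():
                assert (min(u, v), max(u, v)) in msn
            net = build_mj_network(
                profiles_from_vectors(vecs, loci=("L1", "L2", "L3", "L4"))
            )
            # Steiner cost of the MJ network (its own spanning tree, median
            # nodes included) never exceeds the observed-only MST cost
            steiner = nx.minimum_spanning_tree(net.graph).size(weight="weight")
            assert steiner <= mst_cost + 1e-9

    def test_duplicate_haplotype_only_changes_frequency(self):
        vecs = [(10, 10, 10), (12, 10, 10), (12, 12, 10), (10, 11, 13)]
        base = build_mj_network(profiles_from_vectors(vecs))
        dup = build_mj_network(profiles_from_vectors(vecs + [vecs[1]]))
        base_haps = {base.haplotype_of(n) for n in base.graph.nodes}
        dup_haps = {dup.haplotype_of(n) for n in dup.graph.nodes}
        assert base_haps == dup_haps
        base_edges = {
            frozenset((base.haplotype_of(u), base.haplotype_of(v)))
            for u, v in base.graph.edges
        }
        dup_edges = {
            frozenset((dup.haplotype_of(u), dup.haplotype_of(v)))
            for u, v in dup.graph.edges
        }
        assert base_edges == dup_edges
        node = next(
            n for n in dup.graph.nodes if dup.haplotype_of(n) == vecs[1]
        )
        assert dup.graph.nodes[node]["frequency"] == 2

    def test_frequencies_sum_to_sample_count(self):
        rng = np.random.default_rng(3)
        vecs = [tuple(int(x) for x in rng.integers(10, 13, size=3)) for _ in range(20)]
        net = build_mj_network(profiles_from_vectors(vecs))
        assert net.frequency_sum() == 20

    def test_network_is_connected(self):
        rng = np.random.default_rng(4)
        vecs = [tuple(int(x) for x in rng.integers(8, 15, size=3)) for _ in range(12)]
        net = build_mj_network(profiles_from_vectors(vecs))
        assert nx.is_connected(net.graph)

    def test_epsilon_monotonicity_of_msn(self):
        rng = np.random.default_rng(5)
        vecs = list(dict.fromkeys(
            tuple(int(x) for x in rng.integers(9, 14, size=3)) for _ in range(8)
        ))
        wvec = np.ones(3, dtype=np.int64)
        e0 = set(minimum_spanning_network(vecs, wvec, epsilon=0.0))
        e2 = set(minimum_spanning_network(vecs, wvec, epsilon=2.0))
        e5 = set(minimum_spanning_network(vecs, wvec, epsilon=5.0))
        assert e0 <= e2 <= e5

    def test_non_integer_alleles_rejected(self):
        with pytest.raises(ValueError):
            make_profile("x", {"L1": 10.5})


class TestExport:
    def net(self):
        vecs = [(10, 10, 10), (11, 11, 10), (11, 10, 11), (10, 10, 12)]
        pops = ["P1", "P1", "P2", "P2"]
        return build_mj_network(profiles_from_vectors(vecs, pops=pops))

    def test_graphml_round_trip(self, tmp_path):
        net = self.net()
        path = tmp_path / "net.graphml"
        export_network(net, path, fmt="graphml")
        back = read_graphml_network(path)
        assert {
            (back.nodes[n]["haplotype"], back.nodes[n]["kind"], back.nodes[n]["frequency"])
            for n in back.nodes
        } == {
            (net.haplotype_of(n), net.graph.nodes[n]["kind"], net.graph.nodes[n]["frequency"])
            for n in net.graph.nodes
        }
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in net.graph.edges}

    def test_single_node_graphml(self, tmp_path):
        net = build_mj_network(profiles_from_vectors([(10, 10, 10)] * 3))
        path = tmp_path / "one.graphml"
        export_network(net, path, fmt="graphml")
        back = read_graphml_network(path)
        assert back.number_of_nodes() == 1 and back.number_of_edges() == 0

    def test_dot_has_unique_ids(self, tmp_path):
        net = self.net()
        path = tmp_path / "net.dot"
        export_network(net, path, fmt="dot")
        lines = path.read_text().splitlines()
        ids = [l.split()[0] for l in lines if l.strip().startswith("n") and "[label" in l and "--" not in l]
        assert len(ids) == len(set(ids)) == net.graph.number_of_nodes()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(self.net(), tmp_path / "x", fmt="nexus")
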