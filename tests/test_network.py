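"""Median-joining network construction, center finding and export."""

import itertools
import random

import networkx as nx
import pytest

from haplopipe import (
    build_mj_network,
    export_network,
    identify_center,
    import_network,
    minimum_spanning_network,
    motif,
    motif_distance,
    networks_equal,
    tabulate_haplotypes,
)
from haplopipe.network import MEDIAN, OBSERVED


def _nx_mst_weight(haplotypes, weights=None):
    """Independent MST oracle on the complete observed graph."""
    g = nx.Graph()
    nodes = list(haplotypes)
    for a, b in itertools.combinations(nodes, 2):
        g.add_edge(a, b, weight=motif_distance(a, b, weights))
    if len(nodes) == 1:
        return 0.0
    mst = nx.minimum_spanning_tree(g, weight="weight")
    return sum(d["weight"] for _, _, d in mst.edges(data=True)), mst


class TestBuildMJNetwork:
    def test_single_haplotype(self, s1):
        net = build_mj_network({s1: 5})
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0
        assert net.frequency(s1) == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_mj_network({})

    def test_three_haplotype_star_with_observed_center(self, s1, s2, ancestral):
        """S1 and S2 each one step from the ancestral motif: a 2-edge star.

        The ancestral motif is itself the majority consensus of the
        triplet, so no median vector is added.
        """
        net = build_mj_network({s1: 10, s2: 4, ancestral: 1})
        assert net.graph.number_of_nodes() == 3
        edges = {frozenset((u, v)): d for u, v, d in net.graph.edges(data=True)}
        assert set(edges) == {frozenset((s1, ancestral)), frozenset((s2, ancestral))}
        assert edges[frozenset((s1, ancestral))]["weight"] == 1
        assert edges[frozenset((s1, ancestral))]["positions"] == (16223,)
        assert edges[frozenset((s2, ancestral))]["positions"] == (16309,)
        assert all(d["kind"] == OBSERVED for _, d in net.graph.nodes(data=True))

    def test_median_vector_added_for_unsampled_ancestor(self):
        """Three singleton derivatives of an unsampled type get a median hub."""
        u, v, w = motif([16100]), motif([16200]), motif([16300])
        net = build_mj_network({u: 1, v: 1, w: 1})
        medians = [n for n, d in net.graph.nodes(data=True) if d["kind"] == MEDIAN]
        assert medians == [motif([])]
        assert net.frequency(medians[0]) == 0
        assert net.graph.degree[medians[0]] == 3
        assert net.graph.number_of_edges() == 3  # star through the median

    def test_cohort_network_contains_all_observed_with_frequencies(self, study):
        table = tabulate_haplotypes(study.samples)
        net = build_mj_network(table.counts)
        assert nx.is_connected(net.graph)
        for m, count in table.counts.items():
            assert net.graph.nodes[m]["kind"] == OBSERVED
            assert net.frequency(m) == count
        assert net.n_samples == 20

    def test_msn_contains_an_independent_mst(self, study):
        """The epsilon=0 spanning network is the union of all MSTs."""
        table = tabulate_haplotypes(study.samples)
        msn = minimum_spanning_network(table.counts)
        weight, mst = _nx_mst_weight(table.counts)
        for u, v in mst.edges:
            assert msn.graph.has_edge(u, v)
        # and every MSN edge weight equals the pair's minimax merge level,
        # so a spanning tree inside the MSN achieves the oracle MST weight
        tree = nx.minimum_spanning_tree(msn.graph, weight="weight")
        assert sum(d["weight"] for _, _, d in tree.edges(data=True)) == weight

    def test_median_vectors_never_increase_spanning_cost(self, study):
        table = tabulate_haplotypes(study.samples)
        weight, _ = _nx_mst_weight(table.counts)
        net = build_mj_network(table.counts)
        tree = nx.minimum_spanning_tree(net.graph, weight="weight")
        assert sum(d["weight"] for _, _, d in tree.edges(data=True)) <= weight

    def test_construction_invariant_to_input_order(self, study):
        table = tabulate_haplotypes(study.samples)
        items = list(table.counts.items())
        nets = []
        for seed in (0, 1):
            random.Random(seed).shuffle(items)
            nets.append(build_mj_network(dict(items)))
        assert networks_equal(nets[0], nets[1])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_tree_generated_data_recovered_without_reticulation(self, seed):
        """With every node of a mutation tree sampled and epsilon=0, the
        network is exactly that tree (each edge adds one fresh site)."""
        rng = random.Random(seed)
        positions = iter(rng.sample(range(16035, 16410), 30))
        tree_nodes = [motif([])]
        tree_edges = []
        while len(tree_nodes) < 8:
            parent = rng.choice(tree_nodes)
            child = motif(sorted(parent.positions | {next(positions)}))
            tree_nodes.append(child)
            tree_edges.append(frozenset((parent, child)))
        net = build_mj_network({n: 1 for n in tree_nodes}, epsilon=0.0)
        assert net.graph.number_of_nodes() == 8
        assert {frozenset((u, v)) for u, v in net.graph.edges} == set(tree_edges)

    def test_length_variant_masking_merges_poly_c_variants(self):
        a = motif([16189, 16311])
        b = motif([16189, 16192, 16311])  # differs only inside the poly-C region
        net = build_mj_network({a: 2, b: 3}, mask_length_variants=True)
        assert net.graph.number_of_nodes() == 1
        assert net.n_samples == 5


class TestIdentifyCenter:
    def test_star_center(self, s1, s2, ancestral):
        net = build_mj_network({s1: 1, s2: 1, ancestral: 1})
        assert identify_center(net) == ancestral

    def test_path_graph_middle_node(self):
        a, b, c = motif([16100]), motif([16100, 16200]), motif([16100, 16200, 16300])
        net = build_mj_network({a: 1, b: 1, c: 1})
        assert identify_center(net) == b

    def test_matches_exhaustive_evaluation(self, study):
        """Frequency-weighted eccentricity brute-forced over every node."""
        table = tabulate_haplotypes(study.samples)
        net = build_mj_network(table.counts)
        sp = dict(nx.all_pairs_dijkstra_path_length(net.graph, weight="weight"))
        scores = {
            node: sum(net.frequency(o) * sp[node][o] for o in net.graph.nodes)
            for node in net.graph.nodes
        }
        best = min(scores.values())
        winners = {n for n, v in scores.items() if v == best}
        center = identify_center(net)
        assert center in winners
        assert center == min(winners, key=lambda m: m.sort_key())

    def test_unbalanced_star_center_follows_frequency(self, s1, s2, ancestral):
        net = build_mj_network({s1: 10, s2: 4, ancestral: 1})
        # brute force: S1 wins (0*10 + 2*4 + 1*1 = 9 beats A's 14)
        assert identify_center(net) == s1


class TestExport:
    def test_graphml_roundtrip(self, study):
        import tempfile
        from pathlib import Path

        table = tabulate_haplotypes(study.samples)
        net = build_mj_network(table.counts)
        with tempfile.TemporaryDirectory() as d:
            path = export_network(net, Path(d) / "net.graphml", "graphml")
            loaded = import_network(path)
        assert networks_equal(net, loaded)
        assert loaded.epsilon == net.epsilon
        assert loaded.window == net.window

    def test_graphml_roundtrip_with_crs_node_and_weights(self):
        u, v, w = motif([16100]), motif([16200]), motif([16300])
        net = build_mj_network({u: 1, v: 1, w: 1}, weights={16100: 2.0})
        import tempfile
        from pathlib import Path

        with tempfile.TemporaryDirectory() as d:
            loaded = import_network(export_network(net, Path(d) / "n.graphml"))
        assert networks_equal(net, loaded)
        assert loaded.weights == {16100: 2.0}

    def test_dot_and_edgelist_outputs(self, tmp_path, s1, s2, ancestral):
        net = build_mj_network({s1: 10, s2: 4, ancestral: 1})
        dot = export_network(net, tmp_path / "net.dot", "dot")
        text = dot.read_text()
        assert text.count("--") == 2 and "n=10" in text
        tsv = export_network(net, tmp_path / "net.tsv", "tsv-edgelist")
        lines = tsv.read_text().strip().splitlines()
        assert lines[0] == "source\ttarget\tweight\tpositions"
        assert len(lines) == 3

    def test_single_node_exports(self, tmp_path, s1):
        net = build_mj_network({s1: 1})
        path = export_network(net, tmp_path / "one.graphml")
        assert networks_equal(import_network(path), net)

    def test_unknown_format_rejected(self, tmp_path, s1):
        with pytest.raises(ValueError):
            export_network(build_mj_network({s1: 1}), tmp_path / "x", "svg")
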