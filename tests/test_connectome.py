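import hashlib
from importlib import resources

import numpy as np
import pytest

from bittercircuit.connectome import (
    CircuitGraph,
    Neuron,
    downstream_layer,
    feedback_detect,
    find_paths,
    interconnection_matrix,
    load_circuit_table,
    load_neuron_annotations,
    load_table1,
    load_table2,
    parse_region_list,
    region_fractions,
    top_targets,
    write_edge_list,
    write_neuron_annotations,
)
from bittercircuit.exceptions import (
    FormatError,
    InvalidParameterError,
    LabelingError,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def brute_downstream(edges, sources, edge_min):
    """Membership + totals by direct edge enumeration."""
    members = {}
    for u, v, w in edges:
        if u in sources and w >= edge_min:
            members.setdefault(v, 0)
            members[v] += w
    return members


def brute_paths(edges, sources, target, max_intermediates, edge_min):
    adj = {}
    for u, v, w in edges:
        if w >= edge_min:
            adj.setdefault(u, []).append((v, w))
    found = []

    def dfs(node, path, weights):
        if len(path) - 2 > max_intermediates:
            return
        if node == target and len(path) > 1:
            found.append((tuple(path), tuple(weights)))
            return
        if node == target:
            return
        for nxt, w in adj.get(node, []):
            if nxt not in path:
                dfs(nxt, path + [nxt], weights + [w])

    for s in sources:
        if s != target:
            dfs(s, [s], [])
    return set(found)


def random_graph(rng, max_nodes=50):
    n = int(rng.integers(8, max_nodes + 1))
    nodes = [f"n{i:02d}" for i in range(n)]
    graph = CircuitGraph()
    subtypes = {}
    for i, cid in enumerate(nodes):
        subtype = f"T{i % 3}"
        subtypes[cid] = subtype
        graph.add_neuron(Neuron(cell_id=cid, cell_type=subtype, subtype_group=subtype))
    n_edges = int(rng.integers(n, 3 * n))
    edges = {}
    for _ in range(n_edges):
        u, v = rng.choice(nodes, 2, replace=False)
        edges[(str(u), str(v))] = int(rng.integers(1, 13))
    for (u, v), w in edges.items():
        graph.add_edge(u, v, w)
    edge_list = [(u, v, w) for (u, v), w in edges.items()]
    sources = set(str(s) for s in rng.choice(nodes, size=max(2, n // 5), replace=False))
    return graph, edge_list, sources, subtypes


# ---------------------------------------------------------------------------
# packaged reference tables

FIXTURE_SHA256 = {
    "table1_3n.tsv": "3d7519546a58543e01461be3ea8401fae7a9fd722198c76a0c44ff3b27b97611",
    "table2_4n.tsv": "c3a18a3d729732e87a4256d83a3f3fa93d740b2b33782a0b4459e83a90e7e698",
}


class TestReferenceTables:
    @pytest.mark.parametrize("name,expected", sorted(FIXTURE_SHA256.items()))
    def test_fixture_checksums_guard_transcription_drift(self, name, expected):
        data = resources.files("bittercircuit.data").joinpath(name).read_bytes()
        assert hashlib.sha256(data).hexdigest() == expected

    def test_top_3n_table_loads_one_member_per_row(self):
        table = load_table1()
        assert len(table.layer) == 32
        assert table.layer.totals().max() == 64  # strongest single 3N input
        assert all(m.total_input >= 20 for m in table.layer.members.values())

    def test_top_4n_table_loads_with_ranking_bounds(self):
        table = load_table2()
        assert len(table.layer) == 30
        totals = table.layer.totals()
        assert totals.min() == 96 and totals.max() == 363

    def test_population_rule_reproduces_top_3n_count(self):
        layer = load_table1().layer
        assert len(top_targets(layer, "population_min", k=20)) == 32

    def test_top_30_rule_reproduces_4n_threshold(self):
        layer = load_table2().layer
        top = top_targets(layer, "top_n", n=30)
        assert len(top) == 30 and top.totals().min() == 96

    @pytest.mark.parametrize(
        "region,expected", [("SMP", 27 / 30), ("LH", 18 / 30), ("MB", 13 / 30)]
    )
    def test_top_4n_region_projection_fractions(self, region, expected):
        table = load_table2()
        fractions = region_fractions(table.members_as_neurons(), side_rule="ipsi_only")
        assert fractions[region] == pytest.approx(expected)

    def test_contralateral_annotations_parsed(self):
        table = load_table1()
        cell = table.neurons["421650982"]  # projects to SMP both ipsi and contra
        assert ("SMP", "contra") in cell.output_regions
        assert ("SMP", "ipsi") in cell.output_regions


class TestParsingAndIO:
    def test_region_list_tolerates_stray_commas(self):
        regions = parse_region_list("AVLP, LH,, MB, SMP(C),")
        assert regions == [("AVLP", "ipsi"), ("LH", "ipsi"), ("MB", "ipsi"), ("SMP", "contra")]

    def test_edge_list_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        graph, _, _, _ = random_graph(rng, max_nodes=20)
        path = tmp_path / "edges.tsv"
        write_edge_list(graph, path)
        reread = load_circuit_table(path, dialect="edge_list")
        assert sorted(reread.edges()) == sorted(graph.edges())

    def test_empty_edge_list_gives_empty_graph(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("pre_id\tpost_id\tweight\n")
        graph = load_circuit_table(path, dialect="edge_list")
        assert graph.n_neurons == 0

    def test_duplicate_edges_are_aggregated(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("pre_id\tpost_id\tweight\na\tb\t3\na\tb\t4\n")
        graph = load_circuit_table(path, dialect="edge_list")
        assert graph.edge_weight("a", "b") == 7

    def test_unknown_region_token_policy(self, tmp_path):
        path = tmp_path / "summary.tsv"
        path.write_text(
            "type\tID\tn_in\tin_types\tn_syn\tpct\tregions\n"
            "X1\t100\t2\tmAL3A\t25\t1.0\tSLP, XYZ\n"
        )
        with pytest.warns(UserWarning, match="XYZ"):
            load_circuit_table(path, dialect="summary_table")
        with pytest.raises(FormatError):
            load_circuit_table(path, dialect="summary_table", unknown_region="reject")

    def test_annotation_round_trip(self, tmp_path):
        neurons = {
            "a": Neuron("a", "mAL3A", "mAL3A", [("SLP", "ipsi"), ("SMP", "contra")], 1200),
            "b": Neuron("b", "3N", None, [("LH", "ipsi")], None),
        }
        path = tmp_path / "ann.tsv"
        write_neuron_annotations(neurons, path)
        reread = load_neuron_annotations(path)
        assert reread["a"] == neurons["a"]
        assert reread["b"].output_regions == [("LH", "ipsi")]


class TestDownstreamLayer:
    def chain_graph(self):
        g = CircuitGraph()
        for cid, ctype in [("s1", "seed"), ("s2", "seed"), ("a", "3N"), ("b", "3N"), ("c", "4N")]:
            g.add_neuron(Neuron(cell_id=cid, cell_type=ctype))
        g.add_edge("s1", "a", 5)
        g.add_edge("s2", "a", 2)  # sub-threshold contribution
        g.add_edge("s1", "b", 2)  # never qualifies
        g.add_edge("a", "c", 7)
        return g

    def test_per_edge_admission_rule(self):
        layer = downstream_layer(self.chain_graph(), {"s1", "s2"}, edge_min=3)
        assert layer.member_ids == {"a"}

    def test_total_excludes_subthreshold_edges_by_default(self):
        layer = downstream_layer(self.chain_graph(), {"s1", "s2"}, edge_min=3)
        assert layer.members["a"].total_input == 5

    def test_subthreshold_edges_countable_via_flag(self):
        layer = downstream_layer(
            self.chain_graph(), {"s1", "s2"}, edge_min=3, include_subthreshold_in_total=True
        )
        assert layer.members["a"].total_input == 7

    def test_total_is_sum_of_contributing_edges(self):
        rng = np.random.default_rng(7)
        graph, edges, sources, _ = random_graph(rng)
        layer = downstream_layer(graph, sources, edge_min=3)
        for member in layer.members.values():
            assert member.total_input == sum(w for _, w in member.contributing_edges)

    def test_edge_min_above_max_weight_empties_layer(self):
        layer = downstream_layer(self.chain_graph(), {"s1", "s2"}, edge_min=100)
        assert len(layer) == 0

    def test_raising_edge_min_never_adds_members(self):
        rng = np.random.default_rng(8)
        graph, _, sources, _ = random_graph(rng)
        previous = None
        for edge_min in (1, 3, 5, 8):
            ids = downstream_layer(graph, sources, edge_min=edge_min).member_ids
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_empty_source_set_gives_empty_layer(self):
        assert len(downstream_layer(self.chain_graph(), set(), edge_min=3)) == 0

    def test_unknown_source_rejected(self):
        with pytest.raises(InvalidParameterError):
            downstream_layer(self.chain_graph(), {"ghost"}, edge_min=3)


class TestTopTargets:
    def test_population_min_matches_brute_force(self):
        rng = np.random.default_rng(9)
        graph, edges, sources, _ = random_graph(rng)
        layer = downstream_layer(graph, sources, edge_min=2)
        top = top_targets(layer, "population_min", k=10, exclude=sources)
        oracle = {
            cid
            for cid, total in brute_downstream(edges, sources, 2).items()
            if total >= 10 and cid not in sources
        }
        assert top.member_ids == oracle

    def test_top_n_tie_break_by_cell_id(self):
        from bittercircuit.connectome import LayerMember, LayerResult

        layer = LayerResult(
            layer_index=3,
            members={
                cid: LayerMember(cell_id=cid, total_input=t)
                for cid, t in [("z", 10), ("a", 10), ("m", 5)]
            },
        )
        top = top_targets(layer, "top_n", n=2)
        assert sorted(top.member_ids) == ["a", "z"]

    def test_invalid_n_rejected(self):
        layer = load_table1().layer
        with pytest.raises(InvalidParameterError):
            top_targets(layer, "top_n", n=0)


class TestMotifMatrix:
    def planted_graph(self):
        g = CircuitGraph()
        for cid, st in [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]:
            g.add_neuron(Neuron(cell_id=cid, cell_type=st, subtype_group=st))
        g.add_edge("a1", "b1", 8)
        g.add_edge("a2", "b2", 6)
        g.add_edge("b1", "a1", 3)  # below motif threshold
        return g

    def test_planted_one_way_motif(self):
        m = interconnection_matrix(self.planted_graph(), edge_min=5)
        assert m.loc["A", "B"] == 2
        assert m.values.sum() == 2

    def test_infinite_threshold_zeroes_matrix(self):
        m = interconnection_matrix(self.planted_graph(), edge_min=10**9)
        assert (m.values == 0).all()

    def test_weight_mode_sums_synapses(self):
        m = interconnection_matrix(self.planted_graph(), edge_min=5, mode="weight")
        assert m.loc["A", "B"] == 14

    def test_count_mode_matches_pair_enumeration(self):
        rng = np.random.default_rng(10)
        graph, edges, _, subtypes = random_graph(rng)
        m = interconnection_matrix(graph, subtype_map=subtypes, edge_min=4)
        oracle = {}
        for u, v, w in edges:
            if w >= 4:
                key = (subtypes[u], subtypes[v])
                oracle[key] = oracle.get(key, 0) + 1
        for (si, sj), count in oracle.items():
            assert m.loc[si, sj] == count
        assert m.values.sum() == sum(oracle.values())

    def test_unlabeled_cell_rejected(self):
        g = self.planted_graph()
        g.add_neuron(Neuron(cell_id="x", cell_type="A"))
        g.add_edge("x", "b1", 9)
        with pytest.raises(LabelingError):
            interconnection_matrix(g, cells={"x", "b1"}, subtype_map={"b1": "B"})


class TestRegionFractions:
    def test_single_member_is_indicator(self):
        member = Neuron("a", output_regions=[("SLP", "ipsi")])
        fr = region_fractions([member], catalog=["SLP", "SMP"])
        assert fr["SLP"] == 1.0 and fr["SMP"] == 0.0

    def test_contralateral_only_counts_under_either(self):
        member = Neuron("a", output_regions=[("MB", "contra")])
        assert region_fractions([member], "ipsi_only", ["MB"])["MB"] == 0.0
        assert region_fractions([member], "either", ["MB"])["MB"] == 1.0

    def test_empty_member_set_is_undefined(self):
        fr = region_fractions([], catalog=["SLP"])
        assert np.isnan(fr["SLP"])


class TestFeedbackAndPaths:
    def test_feedback_excluded_below_threshold(self):
        g = CircuitGraph()
        for cid in ("s1", "s2", "m1"):
            g.add_neuron(Neuron(cell_id=cid))
        g.add_edge("s1", "m1", 9)
        g.add_edge("m1", "s1", 6)   # qualifying feedback
        g.add_edge("m1", "s2", 2)   # sub-threshold: no feedback
        layer = downstream_layer(g, {"m1"}, edge_min=3)
        fb = feedback_detect(layer, {"s1", "s2"})
        assert set(fb) == {"s1"}
        assert fb["s1"] == [("m1", 6)]

    def test_planted_two_hop_chain(self):
        g = CircuitGraph()
        for cid in ("s", "a", "t"):
            g.add_neuron(Neuron(cell_id=cid))
        g.add_edge("s", "a", 10)
        g.add_edge("a", "t", 7)
        result = find_paths(g, {"s"}, "t", max_intermediates=3)
        assert len(result) == 1
        assert result.paths[0]["nodes"] == ("s", "a", "t")
        assert result.paths[0]["min_weight"] == 7

    def test_edge_min_above_weights_gives_empty(self):
        g = CircuitGraph()
        for cid in ("s", "t"):
            g.add_neuron(Neuron(cell_id=cid))
        g.add_edge("s", "t", 4)
        assert len(find_paths(g, {"s"}, "t", edge_min=5)) == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            graph, edges, sources, _ = random_graph(rng, max_nodes=18)
            target = "n00"
            result = find_paths(
                graph, sources - {target}, target, max_intermediates=2, edge_min=3
            )
            got = {(p["nodes"], p["weights"]) for p in result.paths}
            assert got == brute_paths(edges, sources - {target}, target, 2, 3)

    def test_ranked_by_bottleneck_then_total(self):
        g = CircuitGraph()
        for cid in ("s", "a", "b", "t"):
            g.add_neuron(Neuron(cell_id=cid))
        g.add_edge("s", "a", 10)
        g.add_edge("a", "t", 3)
        g.add_edge("s", "b", 6)
        g.add_edge("b", "t", 6)
        result = find_paths(g, {"s"}, "t")
        assert [p["min_weight"] for p in result.paths] == [6, 3]
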