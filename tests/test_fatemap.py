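import xml.etree.ElementTree as ET

import networkx as nx
import pytest

from boolfate import (
    build_fate_map,
    clamp_node,
    enumerate_attractors,
    export_fate_map,
    resolve_perturbation,
    trajectory_to_attractor,
)
from boolfate.attractors import Attractor
from boolfate.fatemap import (
    Perturbation,
    fate_map_to_dot,
    fate_map_to_tsv,
    parse_fate_map_tsv,
)
from boolfate.network import parse_expression
from boolfate.phenotype import PhenotypeScheme


@pytest.fixture(scope="module")
def identity2_scheme():
    return PhenotypeScheme(
        labels=("M0", "M1", "M2c"),
        conditions={"M1": parse_expression("X1"),
                    "M2c": parse_expression("X2")},
        fallback_label="M0",
        outcome_class={"M0": "neutral", "M1": "tumor-eliminating",
                       "M2c": "tumor-promoting"})


class TestPerturbationType:
    def test_sign_convention(self):
        assert Perturbation("A", 0, 1).sign == "+"
        assert Perturbation("A", 1, 0).sign == "-"

    def test_clamp_must_flip_constant_value(self):
        with pytest.raises(ValueError, match="differ"):
            Perturbation("A", 1, 1)

    def test_varies_allows_either_clamp(self):
        assert Perturbation("A", "varies", 0).sign == "-"
        assert Perturbation("A", "varies", 1).sign == "+"


class TestResolvePerturbation:
    def test_identity3_single_bit_flip(self, identity3_net):
        source = Attractor(states=((0, 0, 0),))
        found = resolve_perturbation(identity3_net, source, "X1", 1)
        assert len(found) == 1
        destination, entry = found[0]
        assert destination.states == ((1, 0, 0),)
        assert entry == 0

    def test_toggle_cycle_dies_under_clamp(self, toggle_net):
        source, _ = trajectory_to_attractor(toggle_net, (0, 0))
        assert source.period == 2
        found = resolve_perturbation(toggle_net, source, "X", 1)
        # both cycle states drain to the same fixed point of the clamped net
        assert len(found) == 1
        destination = found[0][0]
        assert destination.states == ((1, 0),)

    def test_clamp_to_current_value_is_identity_on_fixed_points(
            self, identity3_net):
        source = Attractor(states=((1, 0, 1),))
        found = resolve_perturbation(identity3_net, source, "X1", 1)
        assert found[0][0].states == source.states

    def test_unknown_node(self, toggle_net):
        source = Attractor(states=((0, 1),))
        with pytest.raises(KeyError):
            resolve_perturbation(toggle_net, source, "Q", 1)

    def test_destination_is_attractor_of_clamped_net(self, ring3_net):
        attr_set = enumerate_attractors(ring3_net, mode="exhaustive")
        for source in attr_set.attractors:
            for node in ring3_net.nodes:
                for value in (0, 1):
                    clamped = clamp_node(ring3_net, node, value)
                    for destination, _ in resolve_perturbation(
                            ring3_net, source, node, value):
                        # re-verify the cycle under the clamped dynamics
                        for i, s in enumerate(destination.states):
                            nxt = destination.states[
                                (i + 1) % destination.period]
                            assert clamped.step(s) == nxt
                            assert s[ring3_net.node_index(node)] == value


class TestBuildFateMap:
    def test_identity2_eight_edges(self, identity2_scheme):
        from boolfate import analytic_fixture
        net = analytic_fixture("identity_2").network
        attr_set = enumerate_attractors(net, mode="exhaustive")
        fmap = build_fate_map(net, attr_set, identity2_scheme)
        assert len(fmap.edges) == 8  # 4 fixed points x 2 nodes
        for e in fmap.edges:
            src = fmap.vertices[e.source_key].states[0]
            dst = fmap.vertices[e.destination_key].states[0]
            assert sum(a != b for a, b in zip(src, dst)) == 1

    def test_toggle_full_map(self, toggle_net, toggle_scheme):
        attr_set = enumerate_attractors(toggle_net, mode="exhaustive")
        fmap = build_fate_map(toggle_net, attr_set, toggle_scheme)
        cycle_key = ((0, 0), (1, 1))
        cycle_edges = [e for e in fmap.edges
                       if fmap.vertices[e.source_key].states == cycle_key]
        # the cycle's nodes vary across its states: both clamps per node
        assert len(cycle_edges) == 4
        for e in cycle_edges:
            assert e.perturbation.original_value == "varies"
            destination = fmap.vertices[e.destination_key]
            assert destination.period == 1  # every clamp kills the cycle

    def test_deterministic(self, macrophage, scheme):
        net = macrophage.network
        attr_set = enumerate_attractors(net, mode="exhaustive")
        subset = type(attr_set)(network=net,
                                attractors=attr_set.attractors[:8],
                                mode=attr_set.mode, coverage=attr_set.coverage)
        tsv_a = fate_map_to_tsv(build_fate_map(net, subset, scheme))
        tsv_b = fate_map_to_tsv(build_fate_map(net, subset, scheme))
        assert tsv_a == tsv_b

    def test_fixed_point_sources_single_destination(self, identity3_net,
                                                    identity2_scheme):
        scheme = PhenotypeScheme(
            labels=("M0", "M1"),
            conditions={"M1": parse_expression("X1")},
            fallback_label="M0",
            outcome_class={"M0": "neutral", "M1": "tumor-eliminating"})
        attr_set = enumerate_attractors(identity3_net, mode="exhaustive")
        fmap = build_fate_map(identity3_net, attr_set, scheme)
        per_pert = {}
        for e in fmap.edges:
            key = (e.source_key, e.perturbation)
            per_pert[key] = per_pert.get(key, 0) + 1
        assert all(v == 1 for v in per_pert.values())

    def test_transient_mode_differs_when_flip_decays(self, toggle_scheme):
        from boolfate import parse_network
        net = parse_network("targets, factors\nX, 0\nY, X", "bnet")
        attr_set = enumerate_attractors(net, mode="exhaustive")
        scheme = PhenotypeScheme(
            labels=("M0", "M1"),
            conditions={"M1": parse_expression("X")},
            fallback_label="M0",
            outcome_class={"M0": "neutral", "M1": "tumor-eliminating"})
        clamp_map = build_fate_map(net, attr_set, scheme, mode="clamp")
        trans_map = build_fate_map(net, attr_set, scheme, mode="transient")
        # clamping X=1 holds it on; a transient flip decays back to 0
        clamp_dest = {fmap_dest.states
                      for fmap_dest in clamp_map.vertices.values()}
        assert ((1, 1),) in clamp_dest
        trans_dest = {v.states for v in trans_map.vertices.values()}
        assert ((1, 1),) not in trans_dest

    def test_node_subset(self, toggle_net, toggle_scheme):
        attr_set = enumerate_attractors(toggle_net, mode="exhaustive")
        fmap = build_fate_map(toggle_net, attr_set, toggle_scheme,
                              nodes=["X"])
        assert all(e.perturbation.node == "X" for e in fmap.edges)

    def test_flip_involution_reachability(self, identity3_net):
        # clamp X1 0->1 from (0,0,0), then clamp back 1->0 from the
        # destination: an attractor of the re-clamped network is reached
        source = Attractor(states=((0, 0, 0),))
        dest = resolve_perturbation(identity3_net, source, "X1", 1)[0][0]
        back = resolve_perturbation(identity3_net, dest, "X1", 0)[0][0]
        reclamped = clamp_node(identity3_net, "X1", 0)
        for i, s in enumerate(back.states):
            assert reclamped.step(s) == back.states[(i + 1) % back.period]


@pytest.fixture(scope="module")
def small_map(toggle_net, toggle_scheme):
    attr_set = enumerate_attractors(toggle_net, mode="exhaustive")
    return build_fate_map(toggle_net, attr_set, toggle_scheme)


class TestExport:
    def test_tsv_round_trip(self, small_map, tmp_path):
        path = tmp_path / "map.tsv"
        export_fate_map(small_map, path, "tsv")
        rows = parse_fate_map_tsv(path.read_text())
        assert len(rows) == len(small_map.edges)
        for row, edge in zip(rows, small_map.edges):
            assert row["node"] == edge.perturbation.node
            assert row["sign"] == edge.perturbation.sign
            assert row["destination"] == small_map.vertex_name(
                edge.destination_key)

    def test_tsv_single_edge(self, toggle_net, toggle_scheme, tmp_path):
        attr_set = enumerate_attractors(toggle_net, mode="exhaustive")
        fmap = build_fate_map(toggle_net, attr_set, toggle_scheme,
                              nodes=["X"])
        fmap.edges = fmap.edges[:1]
        path = tmp_path / "one.tsv"
        export_fate_map(fmap, path, "tsv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2  # header + one data row

    def test_graphml_is_wellformed_and_loadable(self, small_map, tmp_path):
        path = tmp_path / "map.graphml"
        export_fate_map(small_map, path, "graphml")
        root = ET.parse(path).getroot()
        assert root.tag == "{http://graphml.graphdrawing.org/xmlns}graphml"
        loaded = nx.read_graphml(path)
        assert loaded.number_of_edges() == len(small_map.edges)
        assert loaded.number_of_nodes() == len(small_map.vertices)

    def test_dot_output(self, small_map, tmp_path):
        path = tmp_path / "map.dot"
        export_fate_map(small_map, path, "dot")
        text = path.read_text()
        assert text.startswith("digraph")
        assert text.count("->") == len(small_map.edges)

    def test_byte_stable(self, small_map, tmp_path):
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_fate_map(small_map, a, "tsv")
        export_fate_map(small_map, b, "tsv")
        assert a.read_bytes() == b.read_bytes()

    def test_unsupported_format(self, small_map, tmp_path):
        with pytest.raises(ValueError, match="format"):
            export_fate_map(small_map, tmp_path / "x.xyz", "xyz")

    def test_empty_map_refused(self, toggle_net, toggle_scheme, tmp_path):
        from boolfate.fatemap import FateMap
        empty = FateMap(toggle_net, toggle_scheme)
        with pytest.raises(ValueError, match="empty"):
            export_fate_map(empty, tmp_path / "x.tsv", "tsv")


def test_dot_text_contains_labels(toggle_net, toggle_scheme):
    attr_set = enumerate_attractors(toggle_net, mode="exhaustive")
    fmap = build_fate_map(toggle_net, attr_set, toggle_scheme)
    dot = fate_map_to_dot(fmap)
    assert '"+X"' in dot or '"-X"' in dot
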