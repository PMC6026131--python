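import math

import networkx as nx
import numpy as np
import pytest

from pialnet.errors import NoBackboneError
from pialnet.netcore import EdgeRecord, NodeRecord, PialNetwork
from pialnet.synthgen import generate_animal_network, generate_geometry
from pialnet.topology import (attachment_region, decompose, identify_lma_edges,
                              loop_count, vertex_offshoot_ratio,
                              watershed_polyline)

from _oracles import brute_force_bridges, spanning_tree_cycle_count
from conftest import make_network


def random_test_network(seed, n_nodes=12, n_edges=None):
    """A random connected multigraph dressed up as a PialNetwork."""
    rng = np.random.default_rng(seed)
    if n_edges is None:
        n_edges = int(rng.integers(n_nodes - 1, 31))
    g = nx.gnm_random_graph(n_nodes, min(n_edges, n_nodes * (n_nodes - 1) // 2),
                            seed=int(rng.integers(0, 2**31)))
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp)
    nodes = [(f"n{i}", rng.uniform(0, 5), rng.uniform(0, 5), "pa")
             for i in comp]
    edges = [(f"e{k}", f"n{a}", f"n{b}") for k, (a, b) in enumerate(g.edges)]
    # sprinkle some parallel edges
    for j in range(int(rng.integers(0, 3))):
        if edges:
            _, a, b = edges[int(rng.integers(0, len(edges)))]
            edges.append((f"m{j}", a, b))
    return make_network(nodes, edges)


class TestDecompose:
    def test_square_cycle_with_two_pa_offshoots(self, square_cycle_with_offshoots):
        dec = decompose(square_cycle_with_offshoots)
        assert dec.backbone_edge_ids == {"e1", "e2", "e3", "e4"}
        assert len(dec.offshoots) == 2
        assert sorted(dec.vertices_per_offshoot) == [1, 1]

    def test_bifurcating_offshoot_counts_three_vertices(self):
        nodes = [("a", 0, 0, "bifurcation"), ("b", 1, 0, "bifurcation"),
                 ("c", 1, 1, "bifurcation"), ("d", 0, 1, "bifurcation"),
                 ("s", 2, 0, "bifurcation"),
                 ("p1", 3, 0.3, "pa"), ("p2", 3, -0.3, "pa")]
        edges = [("e1", "a", "b"), ("e2", "b", "c"), ("e3", "c", "d"),
                 ("e4", "d", "a", "lma"),
                 ("o1", "b", "s"), ("o2", "s", "p1"), ("o3", "s", "p2")]
        net = make_network(nodes, edges)
        # oracle: exhaustive bridge enumeration on the 7-edge graph
        bridges = brute_force_bridges(net)
        assert bridges == {"o1", "o2", "o3"}
        dec = decompose(net)
        assert dec.backbone_edge_ids == {"e1", "e2", "e3", "e4"}
        assert len(dec.offshoots) == 1
        assert dec.offshoots[0].n_vertices == 3
        assert dec.offshoots[0].member_node_ids == {"s", "p1", "p2"}

    def test_acyclic_network_has_no_backbone(self):
        net = make_network(
            [("a", 0, 0, "pa"), ("b", 1, 0, "pa"), ("c", 2, 0, "pa")],
            [("e1", "a", "b"), ("e2", "b", "c")])
        with pytest.raises(NoBackboneError):
            decompose(net)

    def test_pa_on_backbone_is_a_zero_length_offshoot(self):
        nodes = [("a", 0, 0, "pa"), ("b", 1, 0, "pa"),
                 ("c", 1, 1, "pa"), ("d", 0, 1, "pa")]
        edges = [("e1", "a", "b"), ("e2", "b", "c"), ("e3", "c", "d"),
                 ("e4", "d", "a")]
        dec = decompose(make_network(nodes, edges))
        assert len(dec.offshoots) == 4
        assert dec.vertices_per_offshoot == [1, 1, 1, 1]
        assert all(not o.member_edge_ids for o in dec.offshoots)

    @pytest.mark.parametrize("seed", range(100))
    def test_backbone_matches_removal_oracle_on_random_graphs(self, seed):
        net = random_test_network(seed)
        if not net.edges:
            return
        bridges = brute_force_bridges(net)
        all_ids = {e.id for e in net.edges}
        if bridges == all_ids:
            with pytest.raises(NoBackboneError):
                decompose(net)
            return
        dec = decompose(net)
        assert dec.backbone_edge_ids == all_ids - bridges
        # partition property: offshoot edges are exactly the bridges
        off_edges = set().union(*(o.member_edge_ids for o in dec.offshoots)) \
            if dec.offshoots else set()
        assert off_edges == bridges
        assert off_edges.isdisjoint(dec.backbone_edge_ids)


class TestLoopCount:
    def test_tree_and_single_cycle(self, square_cycle_with_offshoots):
        tree = make_network([("a", 0, 0, "pa"), ("b", 1, 0, "pa")],
                            [("e", "a", "b")])
        assert loop_count(tree) == 0
        assert loop_count(square_cycle_with_offshoots) == 1

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_spanning_tree_oracle(self, seed):
        net = random_test_network(seed + 500)
        assert loop_count(net) == spanning_tree_cycle_count(net)

    def test_generated_networks_loop_count_equals_truth(self, one_animal):
        assert loop_count(one_animal.network) == len(one_animal.truth.lma_edge_ids)


class TestIdentifyLma:
    def test_label_mode_returns_ground_truth(self, one_animal):
        got = identify_lma_edges(one_animal.network, "labels")
        assert got == one_animal.truth.lma_edge_ids

    def test_bridges_are_never_anastomoses(self, one_animal):
        bridges = brute_force_bridges(one_animal.network)
        for mode in ("labels", "geometric"):
            assert identify_lma_edges(one_animal.network, mode).isdisjoint(bridges)

    def test_geometric_mode_recovers_truth_on_generated_cohorts(self, default_params):
        n_true = n_found = n_false = 0
        for seed in range(25):
            rng = np.random.default_rng(31_000 + seed)
            rm = generate_geometry(default_params, rng)
            s = generate_animal_network(rm, default_params, "sham", rng)
            got = identify_lma_edges(s.network, "geometric")
            truth = s.truth.lma_edge_ids
            n_true += len(truth)
            n_found += len(got & truth)
            n_false += len(got - truth)
        assert n_found >= 0.95 * n_true
        assert n_false <= 0.05 * max(n_found, 1)

    def test_no_bifurcations_warns_and_returns_empty(self):
        net = make_network([("a", 0, 0, "pa"), ("b", 1, 0, "pa")],
                           [("e1", "a", "b"), ("e2", "a", "b")])
        with pytest.warns(UserWarning):
            assert identify_lma_edges(net, "geometric") == set()


class TestVertexOffshootRatio:
    def _dec_with_vertices(self, counts):
        from pialnet.topology import Offshoot, OffshootDecomposition
        offs = [Offshoot(f"a{i}", set(), set(), v) for i, v in enumerate(counts)]
        return OffshootDecomposition(set(), offs)

    def test_ratio_arithmetic(self):
        dec = self._dec_with_vertices([1, 1])
        out = vertex_offshoot_ratio(dec, lambda i: "barrels")
        assert out["barrels"].ratio == 1.0
        dec = self._dec_with_vertices([1, 3])
        out = vertex_offshoot_ratio(dec, lambda i: "visual")
        assert out["visual"].ratio == 2.0

    def test_region_without_offshoots_is_flagged_undefined(self):
        dec = self._dec_with_vertices([2])
        out = vertex_offshoot_ratio(dec, lambda i: "barrels",
                                    regions=["barrels", "visual"])
        assert not out["visual"].defined
        assert math.isnan(out["visual"].ratio)

    def test_ratios_match_truth_label_recount(self, one_animal):
        net, rm, truth = one_animal.network, one_animal.regions, one_animal.truth
        dec = decompose(net)
        region_of = attachment_region(dec, net, rm)
        got = vertex_offshoot_ratio(dec, region_of, regions=sorted(rm.regions))
        # independent recount from ground-truth memberships
        from shapely.geometry import Point
        nodes = net.node_map()
        truth_sum: dict[str, list] = {}
        for idx in range(len(truth.offshoot_attachments)):
            a = nodes[truth.offshoot_attachments[idx]]
            rid = next((r for r in sorted(rm.regions)
                        if rm.regions[r].covers(Point(a.x_mm, a.y_mm))), None)
            if rid is None:
                continue
            s = truth_sum.setdefault(rid, [0, 0])
            s[0] += truth.offshoot_vertices[idx]
            s[1] += 1
        for rid, (nv, no) in truth_sum.items():
            assert got[rid].n_vertices == nv
            assert got[rid].n_offshoots == no

    def test_adding_pa_leaf_increments_vertex_sum_only(self, square_cycle_with_offshoots):
        base = decompose(square_cycle_with_offshoots)
        grown = PialNetwork(
            nodes=square_cycle_with_offshoots.nodes
            + [NodeRecord("p3", -1.0, 0.0, "pa")],
            edges=square_cycle_with_offshoots.edges
            + [EdgeRecord("o3", "p1", "p3")])
        dec = decompose(grown)
        assert len(dec.offshoots) == len(base.offshoots)
        assert sum(dec.vertices_per_offshoot) == sum(base.vertices_per_offshoot) + 1


class TestWatershed:
    def test_single_cross_territory_lma_midpoint(self):
        net = make_network(
            [("a", 0, 0, "pa"), ("b", 0, 2, "pa"), ("c", 1, 1, "pa")],
            [("e1", "a", "c"), ("e2", "b", "c")])
        net.edges.append(EdgeRecord("w", "a", "b", "lma", "MCA", "ACA"))
        assert watershed_polyline(net) == [(0.0, 1.0)]

    def test_no_cross_territory_edges_warns_empty(self, square_cycle_with_offshoots):
        with pytest.warns(UserWarning):
            assert watershed_polyline(square_cycle_with_offshoots) == []

    def test_midpoints_sorted_by_angle_matches_brute_force(self, one_animal):
        from pialnet.topology import edge_midpoint
        net, rm = one_animal.network, one_animal.regions
        cross = [e for e in net.edges
                 if e.kind == "lma" and e.territory_a != e.territory_b]
        if not cross:
            pytest.skip("no cross-territory LMAs drawn for this seed")
        got = watershed_polyline(net, rm)
        c = rm.slab.centroid
        expect = sorted((edge_midpoint(net, e) for e in cross),
                        key=lambda p: math.atan2(p[1] - c.y, p[0] - c.x))
        assert got == expect
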