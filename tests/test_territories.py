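import dataclasses

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from pialnet.errors import ValidationError
from pialnet.netcore import EdgeRecord, NodeRecord, PialNetwork, RegionMap
from pialnet.territories import (CountTable, TerritoryTiling, assign_lma_regions,
                                 assign_pa_regions, build_count_table,
                                 voronoi_tiling)

from _oracles import monte_carlo_cell_areas
from conftest import make_network

UNIT = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])


class TestVoronoi:
    def test_single_seed_owns_the_whole_slab(self):
        t = voronoi_tiling({"p": (0.3, 0.7)}, UNIT)
        assert t.cell_areas_mm2["p"] == pytest.approx(1.0)

    def test_mirror_symmetric_seeds_split_evenly(self):
        t = voronoi_tiling({"l": (0.25, 0.5), "r": (0.75, 0.5)}, UNIT)
        assert t.cell_areas_mm2["l"] == pytest.approx(0.5, abs=1e-9)
        assert t.cell_areas_mm2["r"] == pytest.approx(0.5, abs=1e-9)

    def test_cell_areas_match_monte_carlo_oracle(self):
        rng = np.random.default_rng(99)
        seeds = {f"s{i}": (rng.uniform(0, 1), rng.uniform(0, 1))
                 for i in range(25)}
        t = voronoi_tiling(seeds, UNIT)
        mc = monte_carlo_cell_areas(seeds, UNIT, n=1_000_000,
                                    rng=np.random.default_rng(1))
        slab_area = UNIT.area
        for sid, area in t.cell_areas_mm2.items():
            assert abs(area - mc[sid]) < 0.005 * slab_area

    def test_areas_conserve_slab_area(self, one_animal):
        seeds = {n.id: (n.x_mm, n.y_mm) for n in one_animal.network.pa_nodes()}
        t = voronoi_tiling(seeds, one_animal.regions.slab)
        total = sum(t.cell_areas_mm2.values())
        assert total == pytest.approx(one_animal.regions.slab.area, rel=1e-6)
        assert all(t.cells[s].covers(Point(*t.seeds[s])) for s in t.seeds)

    def test_coincident_seeds_rejected_with_ids(self):
        with pytest.raises(ValidationError, match="a1.*a2|a2.*a1"):
            voronoi_tiling({"a1": (0.5, 0.5), "a2": (0.5, 0.5)}, UNIT)


class TestAssignment:
    def test_cell_inside_region_is_assigned(self, unit_square_regions):
        cell = Polygon([(0.2, 0.2), (0.4, 0.2), (0.4, 0.4), (0.2, 0.4)])
        t = TerritoryTiling({"p": (0.3, 0.3)}, {"p": cell},
                            unit_square_regions.slab)
        assert assign_pa_regions(t, unit_square_regions) == {"p": "barrels"}

    def test_sixty_forty_split_goes_to_majority(self):
        slab = Polygon([(0, 0), (10, 0), (10, 1), (0, 1)])
        rm = RegionMap(slab=slab, regions={
            "visual": Polygon([(0, 0), (6, 0), (6, 1), (0, 1)]),
            "auditory": Polygon([(6, 0), (10, 0), (10, 1), (6, 1)])})
        cell = Polygon([(0, 0), (10, 0), (10, 1), (0, 1)])  # 60% visual
        t = TerritoryTiling({"p": (5.0, 0.5)}, {"p": cell}, slab)
        got = assign_pa_regions(t, rm)
        # cross-check by an independent clipping-area oracle
        assert cell.intersection(rm.regions["visual"]).area == pytest.approx(6.0)
        assert got == {"p": "visual"}

    def test_exact_half_split_breaks_lexicographically_with_warning(self):
        slab = Polygon([(0, 0), (10, 0), (10, 1), (0, 1)])
        rm = RegionMap(slab=slab, regions={
            "barrels": Polygon([(5, 0), (10, 0), (10, 1), (5, 1)]),
            "auditory": Polygon([(0, 0), (5, 0), (5, 1), (0, 1)])})
        cell = Polygon([(0, 0), (10, 0), (10, 1), (0, 1)])
        t = TerritoryTiling({"p": (5.0, 0.5)}, {"p": cell}, slab)
        with pytest.warns(UserWarning, match="half-area"):
            assert assign_pa_regions(t, rm) == {"p": "auditory"}

    def test_majority_outside_all_regions_means_no_region(self, unit_square_regions):
        cell = Polygon([(0.5, 0.5), (1, 0.5), (1, 1), (0.5, 1)])  # 4% in barrels
        t = TerritoryTiling({"p": (0.9, 0.9)}, {"p": cell},
                            unit_square_regions.slab)
        assert assign_pa_regions(t, unit_square_regions) == {"p": None}


class TestLmaAssignment:
    def _net_with_lma(self, a, b):
        return make_network(
            [("a", a[0], a[1], "pa"), ("b", b[0], b[1], "pa")],
            [("x", "a", "b", "lma"), ("y", "a", "b")])

    def test_midpoint_inside_region(self, unit_square_regions):
        net = self._net_with_lma((0.2, 0.3), (0.4, 0.3))
        got = assign_lma_regions(net, unit_square_regions)
        assert got == {"x": "barrels"}

    def test_near_rule_within_cutoff(self, unit_square_regions):
        # midpoint 0.1 above the region's top edge
        net = self._net_with_lma((0.2, 0.7), (0.4, 0.7))
        assert assign_lma_regions(net, unit_square_regions) == {"x": "barrels"}
        assert assign_lma_regions(net, unit_square_regions,
                                  near_cutoff_mm=0.05) == {"x": None}

    def test_matches_brute_force_geometry_oracle(self, one_animal):
        from pialnet.topology import edge_midpoint
        net, rm = one_animal.network, one_animal.regions
        got = assign_lma_regions(net, rm)
        for e in net.lma_edges():
            m = Point(*edge_midpoint(net, e))
            inside = [r for r in sorted(rm.regions) if rm.regions[r].covers(m)]
            if inside:
                assert got[e.id] == inside[0]
            else:
                dists = {r: rm.regions[r].distance(m) for r in rm.regions}
                best = min(sorted(dists), key=lambda r: dists[r])
                expect = best if dists[best] <= 0.3 else None
                assert got[e.id] == expect


class TestCountTable:
    def test_default_cohort_schema(self, default_params):
        from pialnet.synthgen import generate_cohort
        cohort = generate_cohort(dataclasses.replace(
            default_params, n_sham=2, n_plucked=1))
        tab = build_count_table(cohort, "pa")
        assert len(tab) == 3 * 5
        assert set(tab.df.columns) >= {"animal_id", "group", "region",
                                       "area_mm2", "count"}
        # unassigned PAs are excluded, never invented
        for s in cohort:
            rows = tab.df[tab.df.animal_id == s.animal_id]
            assert rows["count"].sum() <= len(s.truth.pa_node_ids)

    def test_dropped_region_yields_no_row(self, one_animal):
        trimmed = RegionMap(slab=one_animal.regions.slab,
                            regions={k: v for k, v in
                                     one_animal.regions.regions.items()
                                     if k != "visual"})
        s2 = dataclasses.replace(one_animal, regions=trimmed)
        tab = build_count_table([s2], "pa")
        assert len(tab) == 4
        assert "visual" not in set(tab.df.region)

    def test_hand_placed_pa_counts(self):
        # 12 PAs on a regular grid in a 4x1 slab split into two regions;
        # every Voronoi cell falls fully inside its region: manual tally
        slab = Polygon([(0, 0), (4, 0), (4, 1), (0, 1)])
        rm = RegionMap(slab=slab, regions={
            "barrels": Polygon([(0, 0), (2, 0), (2, 1), (0, 1)]),
            "visual": Polygon([(2, 0), (4, 0), (4, 1), (2, 1)])})
        xs = [0.25 + 0.25 * i for i in [0, 1, 2, 3, 4, 5]] \
            + [2.25 + 0.25 * i for i in [0, 1, 2, 3, 4, 5]]
        nodes = [(f"pa{i}", x, 0.5, "pa") for i, x in enumerate(xs)]
        edges = [(f"e{i}", f"pa{i}", f"pa{i + 1}") for i in range(11)]
        net = make_network(nodes, edges)

        class S:  # minimal stand-in for an AnimalSample
            animal_id, group, sex, age_days = "m1", "sham", "F", 50
            network, regions = net, rm

        tab = build_count_table([S()], "pa")
        got = tab.df.set_index("region")["count"].to_dict()
        assert got == {"barrels": 6, "visual": 6}

    def test_translation_leaves_assignments_unchanged(self, one_animal):
        from shapely.affinity import translate as shp_translate
        net, rm = one_animal.network, one_animal.regions
        dx, dy = 13.7, -4.2
        moved_net = PialNetwork(
            nodes=[NodeRecord(n.id, n.x_mm + dx, n.y_mm + dy, n.kind)
                   for n in net.nodes],
            edges=[EdgeRecord(e.id, e.node_a, e.node_b, e.kind, e.territory_a,
                              e.territory_b,
                              None if e.polyline is None else
                              [(x + dx, y + dy) for x, y in e.polyline])
                   for e in net.edges],
            slab_id=net.slab_id, metadata=net.metadata)
        moved_rm = RegionMap(
            slab=shp_translate(rm.slab, dx, dy),
            regions={k: shp_translate(v, dx, dy) for k, v in rm.regions.items()})
        a = assign_lma_regions(net, rm)
        b = assign_lma_regions(moved_net, moved_rm)
        assert a == b

    def test_duplicate_rows_and_negative_counts_rejected(self):
        rec = dict(animal_id="m1", group="sham", sex="F", age_days=50,
                   region="barrels", area_mm2=1.0, count=1)
        with pytest.raises(ValidationError):
            CountTable.from_records([rec, rec], "pa")
        with pytest.raises(ValidationError):
            CountTable.from_records([dict(rec, count=-1)], "pa")
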