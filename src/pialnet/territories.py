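"""Perfusion territories and per-region counting.

Each penetrating arteriole (PA) supplies a column of cortex approximated
by its Voronoi cell: the set of slab points nearer to it than to any
other PA.  A PA is attributed to a sensory region only when the majority
of its cell's area lies inside that region; leptomeningeal anastomoses
(LMAs) are attributed by the position of their arc-length midpoint.  The
per-animal × per-region counts, together with region areas and animal
covariates, form the table the count models are fitted to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from shapely import STRtree
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram

from .errors import PialnetError, ValidationError
from .netcore import PialNetwork, RegionMap
from .topology import edge_midpoint

#: Canonical column order of an exported count table.
COUNT_COLUMNS = ("animal_id", "group", "sex", "age_days",
                 "region", "area_mm2", "count", "flavor")


@dataclass
class TerritoryTiling:
    """Voronoi tessellation of PA seeds clipped to the slab."""

    seeds: dict[str, tuple[float, float]]
    cells: dict[str, Polygon]
    slab: Polygon

    @property
    def cell_areas_mm2(self) -> dict[str, float]:
        return {sid: c.area for sid, c in self.cells.items()}


def voronoi_tiling(pa_points: dict[str, tuple[float, float]],
                   slab: Polygon) -> TerritoryTiling:
    """Tile the slab by nearest-PA (Euclidean) territories.

    Unbounded outer cells are realized by clipping to the slab boundary.
    Raises on coincident seeds (their cells would be undefined).
    """
    ids = sorted(pa_points)
    if not ids:
        raise PialnetError("no PA seeds given")
    pts = [pa_points[i] for i in ids]
    # coincident-seed check
    seen: dict[tuple[float, float], str] = {}
    for sid, p in zip(ids, pts):
        key = (round(p[0], 12), round(p[1], 12))
        if key in seen:
            raise ValidationError(
                f"coincident PA seeds: {seen[key]!r} and {sid!r} at {p}")
        seen[key] = sid

    if len(ids) == 1:
        return TerritoryTiling({ids[0]: pts[0]}, {ids[0]: slab}, slab)

    diagram = voronoi_diagram(MultiPoint(pts), envelope=slab.buffer(1.0))
    raw = list(diagram.geoms)
    tree = STRtree(raw)
    cells: dict[str, Polygon] = {}
    for sid, p in zip(ids, pts):
        pt = Point(p)
        idx = tree.query(pt)
        cell = None
        for j in idx:
            if raw[j].covers(pt):
                cell = raw[j]
                break
        if cell is None:  # point on a cell boundary numerically; take nearest
            cell = min(raw, key=lambda g: g.distance(pt))
        cells[sid] = cell.intersection(slab)
    return TerritoryTiling(dict(zip(ids, pts)), cells, slab)


def assign_pa_regions(tiling: TerritoryTiling,
                      rm: RegionMap) -> dict[str, Optional[str]]:
    """Majority-area rule: seed → region holding > half its cell's area.

    An exact half split is broken toward the lexicographically smallest
    tied region (with a warning); a cell whose majority lies outside all
    regions maps to None.
    """
    rids = sorted(rm.regions)
    rtree = STRtree([rm.regions[r] for r in rids])
    out: dict[str, Optional[str]] = {}
    for sid in sorted(tiling.cells):
        cell = tiling.cells[sid]
        area = cell.area
        if area <= 0:
            out[sid] = None
            continue
        overlaps = {}
        for j in rtree.query(cell):
            rid = rids[j]
            ov = cell.intersection(rm.regions[rid]).area
            if ov > 0:
                overlaps[rid] = ov
        half = 0.5 * area
        winners = [r for r, ov in overlaps.items() if ov > half + 1e-12 * area]
        if winners:
            out[sid] = winners[0]
            continue
        ties = [r for r, ov in overlaps.items()
                if abs(ov - half) <= 1e-12 * max(area, 1.0)]
        if ties:
            pick = sorted(ties)[0]
            warnings.warn(f"seed {sid!r}: exact half-area split between "
                          f"{sorted(ties)}; assigned to {pick!r}")
            out[sid] = pick
        else:
            out[sid] = None
    return out


def assign_lma_regions(net: PialNetwork, rm: RegionMap,
                       near_cutoff_mm: float = 0.3) -> dict[str, Optional[str]]:
    """Attribute each LMA edge to the region containing its midpoint.

    A midpoint outside every region is assigned to the nearest region
    boundary within ``near_cutoff_mm``; beyond that it maps to None.
    """
    rids = sorted(rm.regions)
    out: dict[str, Optional[str]] = {}
    for e in net.edges:
        if e.kind != "lma":
            continue
        mx, my = edge_midpoint(net, e)
        p = Point(mx, my)
        hit = None
        for rid in rids:
            if rm.regions[rid].covers(p):
                hit = rid
                break
        if hit is None:
            best, bestd = None, near_cutoff_mm
            for rid in rids:
                d = rm.regions[rid].distance(p)
                if d < bestd - 1e-15 or (best is not None and abs(d - bestd) <= 1e-15
                                         and rid < best):
                    best, bestd = rid, d
            hit = best
        out[e.id] = hit
    return out


# ---------------------------------------------------------------------------
# count table

@dataclass
class CountTable:
    """One row per animal × region with the count-model covariates.

    Columns: C (count), A (area mm²), R (region), S (group), Y (age,
    days), G (sex), M (animal id), plus the flavor that produced C.
    """

    df: pd.DataFrame
    flavor: str

    def __post_init__(self):
        df = self.df
        dup = df.duplicated(subset=["animal_id", "region"])
        if dup.any():
            raise ValidationError("duplicate animal×region rows in count table")
        if (df["count"] < 0).any():
            raise ValidationError("negative counts")
        if (df["area_mm2"] <= 0).any():
            raise ValidationError("non-positive region areas")
        if not (df["count"] == df["count"].astype(int)).all():
            raise ValidationError("counts must be integers")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out["flavor"] = self.flavor
        out.to_csv(path, index=False, columns=list(COUNT_COLUMNS))

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        df = pd.read_csv(path)
        flavors = df["flavor"].unique()
        if len(flavors) != 1:
            raise ValidationError(f"expected a single flavor, got {list(flavors)}")
        return cls(df.drop(columns=["flavor"]), str(flavors[0]))

    @classmethod
    def from_records(cls, records: list[dict], flavor: str) -> "CountTable":
        df = pd.DataFrame.from_records(
            records, columns=[c for c in COUNT_COLUMNS if c != "flavor"])
        return cls(df, flavor)


FLAVORS = ("pa", "lma", "offshoot_vertices", "offshoot_count")


def build_count_table(cohort, flavor: str = "pa",
                      near_cutoff_mm: float = 0.3) -> CountTable:
    """Assemble the per-animal × per-region count table for one flavor.

    ``pa``: majority-rule Voronoi counts; ``lma``: midpoint-rule counts;
    ``offshoot_vertices`` / ``offshoot_count``: vertex sums / offshoot
    numbers per attachment region.  Regions absent from an animal's
    RegionMap yield no row (damaged regions are omitted, not zeroed).
    """
    from .topology import attachment_region, decompose  # cycle-free import

    if flavor not in FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {FLAVORS}")
    records = []
    for sample in cohort:
        net, rm = sample.network, sample.regions
        rids = sorted(rm.regions)
        counts = {r: 0 for r in rids}
        if flavor == "pa":
            seeds = {n.id: (n.x_mm, n.y_mm) for n in net.pa_nodes()}
            if seeds:
                tiling = voronoi_tiling(seeds, rm.slab)
                for sid, rid in assign_pa_regions(tiling, rm).items():
                    if rid is not None:
                        counts[rid] += 1
        elif flavor == "lma":
            for eid, rid in assign_lma_regions(net, rm, near_cutoff_mm).items():
                if rid is not None:
                    counts[rid] += 1
        else:
            dec = decompose(net)   # propagates NoBackboneError
            region_of = attachment_region(dec, net, rm)
            for i, off in enumerate(dec.offshoots):
                rid = region_of(i)
                if rid is not None:
                    counts[rid] += off.n_vertices if flavor == "offshoot_vertices" else 1
        for rid in rids:
            records.append(dict(
                animal_id=sample.animal_id, group=sample.group, sex=sample.sex,
                age_days=sample.age_days, region=rid,
                area_mm2=rm.regions[rid].area, count=counts[rid]))
    return CountTable.from_records(records, flavor)


def tiling_to_geojson(tiling: TerritoryTiling,
                      assignment: Optional[dict[str, Optional[str]]] = None) -> dict:
    """Export a tiling as a GeoJSON FeatureCollection of cell polygons."""
    from shapely.geometry import mapping
    feats = []
    for sid in sorted(tiling.cells):
        props = {"seed_id": sid, "area_mm2": tiling.cells[sid].area}
        if assignment is not None:
            props["assigned_region"] = assignment.get(sid)
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(tiling.cells[sid])})
    return {"type": "FeatureCollection", "features": feats}
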