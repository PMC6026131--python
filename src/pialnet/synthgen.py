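"""Seeded generator of synthetic pial-network cohorts.

The generator emulates the statistical structure the count models assume:

* a flattened-cortex slab (convex, ellipse-like, ~35 mm²) holding five
  disjoint primary sensory region polygons (barrels, forelimb, hindlimb,
  visual, auditory), jittered per animal;
* penetrating arterioles (PAs) as a spatial Poisson process — per-region
  counts ~ Poisson(λ_PA · A_r · e^u · m_r) plus a background process over
  the rest of the slab — with a per-animal log-normal random intercept
  u ~ N(0, σ_u²) shared across regions, and an optional multiplicative
  deprivation effect m on deprived animals' barrels region;
* leptomeningeal anastomoses (LMAs) with region-heterogeneous intensity
  (hindlimb-enriched by default);
* a connected arterial tree whose trunk is closed into loops by the LMA
  chords — exactly one independent cycle per LMA — and whose PAs attach
  via short offshoot stubs, occasionally carrying one extra bifurcation
  and a second PA leaf.

The trunk is a path ordered by angle about the slab centroid; every LMA
chord spans one angular sector and consecutive chords overlap, so the
whole trunk lies on cycles and the bridgeless core of the generated graph
is exactly trunk + chords.  Departure directions at bifurcations are laid
out so that the acute-angle anastomosis criterion holds exactly at chord
endpoints and fails everywhere else, giving unambiguous ground truth for
geometric LMA identification.  All structure is recorded as ground-truth
labels so the analysis pipeline can be tested against construction.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.affinity import rotate, translate
from shapely.geometry import LineString, Point, Polygon

from .errors import DegenerateNetworkError, GenerationError, ValidationError
from .netcore import (EdgeRecord, NodeRecord, PialNetwork,
                      RegionMap, validate_network, write_network, write_regions)
from .territories import CountTable

_TAU = 2.0 * math.pi


def _default_region_areas() -> dict[str, float]:
    return {"barrels": 4.0, "forelimb": 1.5, "hindlimb": 1.0,
            "visual": 3.0, "auditory": 1.5}


def _default_lma_rates() -> dict[str, float]:
    # Not printed in the source study (figure only); declared assumptions.
    # Hindlimb sits on the MCA/PCA watershed and is anastomosis-enriched.
    return {"barrels": 1.0, "forelimb": 1.0, "hindlimb": 2.0,
            "visual": 1.0, "auditory": 1.0}


@dataclass
class GeneratorParams:
    """All intensities, effect multipliers, geometry sizes and seeds.

    Units: areas mm², intensities per mm², ages days.  ``sigma_u`` is the
    SD of the animal-level log-intensity random intercept shared by all
    regions of an animal; ``deprivation_multiplier`` scales the barrels
    intensity of deprived (plucked) animals (1.0 = null effect).
    """

    slab_area_mm2: float = 35.0
    region_areas_mm2: dict = field(default_factory=_default_region_areas)
    lambda_pa_per_mm2: float = 17.4
    lma_rate_per_mm2: dict = field(default_factory=_default_lma_rates)
    sigma_u: float = 0.25
    deprivation_multiplier: float = 1.0
    offshoot_bifurcation_prob: float = 0.25
    n_sham: int = 10
    n_plucked: int = 9
    age_range_days: tuple = (45, 65)
    lma_cross_territory_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.lambda_pa_per_mm2 < 0 or any(v < 0 for v in self.lma_rate_per_mm2.values()):
            raise ValidationError("intensities must be >= 0")
        if self.sigma_u < 0 or self.slab_area_mm2 <= 0:
            raise ValidationError("sigma_u and slab area must be non-negative")
        if any(a <= 0 for a in self.region_areas_mm2.values()):
            raise ValidationError("region areas must be positive")
        if sum(self.region_areas_mm2.values()) >= self.slab_area_mm2:
            raise GenerationError(
                f"region areas sum to {sum(self.region_areas_mm2.values())} mm² "
                f">= slab area {self.slab_area_mm2} mm²")
        for p in (self.offshoot_bifurcation_prob, self.lma_cross_territory_prob):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.deprivation_multiplier < 0:
            raise ValidationError("deprivation_multiplier must be >= 0")
        if self.n_sham < 0 or self.n_plucked < 0:
            raise ValidationError("cohort sizes must be >= 0")


@dataclass
class GroundTruth:
    """Construction labels for everything the pipeline must recover."""

    lma_edge_ids: set[str]
    pa_node_ids: set[str]
    per_region_expected_counts: dict      # region -> {"pa": mu, "lma": mu}
    u_animal: float
    backbone_edge_ids: set[str]
    offshoot_memberships: dict            # node id -> offshoot index
    offshoot_vertices: list[int]          # vertex count per truth offshoot
    offshoot_attachments: list[str]       # attachment node per truth offshoot
    pa_region_counts: dict                # realized PA count per region
    lma_region_counts: dict               # realized LMA count per region


@dataclass
class AnimalSample:
    animal_id: str
    group: str                 # sham | plucked
    sex: str                   # M | F
    age_days: int
    network: PialNetwork
    regions: RegionMap
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geometry

# template centres (mm, for a 35 mm² slab) — rough flattened-cortex layout
_TEMPLATE_CENTRES = {
    "barrels": (0.8, 0.0),
    "forelimb": (0.2, 1.6),
    "hindlimb": (-1.4, 1.5),
    "visual": (-1.8, -0.9),
    "auditory": (1.5, -1.5),
}


def _ellipse_polygon(area: float, aspect: float, n: int = 48) -> Polygon:
    a = math.sqrt(area * aspect / math.pi)
    b = a / aspect
    th = np.linspace(0.0, _TAU, n, endpoint=False)
    poly = Polygon(np.column_stack([a * np.cos(th), b * np.sin(th)]))
    s = math.sqrt(area / poly.area)   # correct discretization deficit
    th = np.linspace(0.0, _TAU, n, endpoint=False)
    return Polygon(np.column_stack([s * a * np.cos(th), s * b * np.sin(th)]))


def generate_geometry(params: GeneratorParams,
                      rng: np.random.Generator) -> RegionMap:
    """Per-animal slab + region polygons at the requested areas (exact),
    with jittered placement, aspect and rotation."""
    params.validate()
    scale = math.sqrt(params.slab_area_mm2 / 35.0)
    for attempt in range(20):
        damp = 1.0 / (1 + attempt)    # shrink jitter on retries
        aspect = rng.uniform(1.25, 1.55)
        slab = _ellipse_polygon(params.slab_area_mm2, aspect)
        regions: dict[str, Polygon] = {}
        ok = True
        for rid in sorted(params.region_areas_mm2):
            area = params.region_areas_mm2[rid]
            cx, cy = _TEMPLATE_CENTRES.get(rid, (0.0, 0.0))
            cx, cy = cx * scale, cy * scale
            ar = rng.uniform(1.1, 1.5)
            w = math.sqrt(area * ar)
            h = area / w
            rect = Polygon([(-w / 2, -h / 2), (w / 2, -h / 2),
                            (w / 2, h / 2), (-w / 2, h / 2)])
            rect = rotate(rect, rng.uniform(-8, 8) * damp, origin=(0, 0))
            rect = translate(rect,
                             cx + rng.uniform(-0.12, 0.12) * damp,
                             cy + rng.uniform(-0.12, 0.12) * damp)
            regions[rid] = rect
        # containment + disjointness
        for rid, poly in regions.items():
            if not slab.buffer(1e-9).contains(poly):
                ok = False
        rids = sorted(regions)
        for i, a in enumerate(rids):
            for b in rids[i + 1:]:
                if regions[a].intersection(regions[b]).area >= 1e-9:
                    ok = False
        if ok:
            return RegionMap(slab=slab, regions=regions)
    raise GenerationError("could not place the requested region areas "
                          "inside the slab after 20 attempts")


def _uniform_in_polygon(poly: Polygon, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n points uniformly inside a polygon."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out = []
    while len(out) < n:
        m = max(16, 2 * (n - len(out)))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        for x, y in zip(xs, ys):
            if poly.contains(Point(x, y)):
                out.append((x, y))
                if len(out) == n:
                    break
    return np.asarray(out)


# ---------------------------------------------------------------------------
# network construction helpers

def _toward(p, target, dist):
    dx, dy = target[0] - p[0], target[1] - p[1]
    n = math.hypot(dx, dy)
    if n < 1e-9:
        dx, dy, n = 1.0, 0.0, 1.0
    return (p[0] + dist * dx / n, p[1] + dist * dy / n)


_ELBOW = 0.03  # mm; length of the departure-direction elbow at bifurcations


def _elbow(p, ang):
    return (p[0] + _ELBOW * math.cos(ang), p[1] + _ELBOW * math.sin(ang))


def _route_chord(p, ang_p, q, ang_q, mid):
    """Polyline p→q through ``mid`` with equal arc length on both sides,
    leaving p and q along the given port angles."""
    ep, eq = _elbow(p, ang_p), _elbow(q, ang_q)
    s1 = _ELBOW + math.dist(ep, mid)
    s2 = _ELBOW + math.dist(eq, mid)

    def bulge(a, b, extra):
        # point c off the a-b midpoint such that |a-c|+|c-b| = |a-b|+extra
        d = math.dist(a, b)
        target = d + extra
        off = math.sqrt(max(0.0, (target / 2) ** 2 - (d / 2) ** 2))
        mx, my = (a[0] + b[0]) / 2, (a[1] + b[1]) / 2
        if d < 1e-12:
            return (mx + off, my)
        nx_, ny_ = -(b[1] - a[1]) / d, (b[0] - a[0]) / d
        return (mx + off * nx_, my + off * ny_)

    if s1 < s2 - 1e-12:
        c = bulge(ep, mid, s2 - s1)
        return [p, ep, c, mid, eq, q]
    if s2 < s1 - 1e-12:
        c = bulge(mid, eq, s1 - s2)
        return [p, ep, mid, c, eq, q]
    return [p, ep, mid, eq, q]


def _norm_ang(a: float) -> float:
    return a % _TAU


def generate_animal_network(regions: RegionMap, params: GeneratorParams,
                            group: str, rng: np.random.Generator,
                            animal_id: str = "m01", sex: str = "F",
                            age_days: int = 55) -> AnimalSample:
    """Draw one animal: counts, point pattern, and the full traced graph.

    See the module docstring for the construction.  The returned sample's
    ground truth records exactly which edges are LMAs, which edges form
    the bridgeless backbone, and the node membership of every offshoot.
    """
    params.validate()
    slab = regions.slab
    cen = (slab.centroid.x, slab.centroid.y)
    u = float(rng.normal(0.0, params.sigma_u)) if params.sigma_u > 0 else 0.0
    eu = math.exp(u)

    # --- counts and point patterns -------------------------------------
    expected = {}
    pa_pts: list[tuple[float, float, Optional[str]]] = []   # (x, y, region)
    pa_region_counts = {}
    for rid in sorted(regions.regions):
        area = regions.regions[rid].area
        m = (params.deprivation_multiplier
             if (group == "plucked" and rid == "barrels") else 1.0)
        mu_pa = params.lambda_pa_per_mm2 * area * eu * m
        mu_lma = params.lma_rate_per_mm2.get(rid, 0.0) * area * eu
        expected[rid] = {"pa": mu_pa, "lma": mu_lma}
        n = int(rng.poisson(mu_pa))
        pa_region_counts[rid] = n
        for x, y in _uniform_in_polygon(regions.regions[rid], n, rng):
            pa_pts.append((x, y, rid))
    bg_area = slab.area - sum(p.area for p in regions.regions.values())
    n_bg = int(rng.poisson(params.lambda_pa_per_mm2 * bg_area * eu))
    region_polys = [regions.regions[r] for r in sorted(regions.regions)]
    placed = 0
    while placed < n_bg:
        for x, y in _uniform_in_polygon(slab, n_bg - placed, rng):
            if not any(rp.contains(Point(x, y)) for rp in region_polys):
                pa_pts.append((x, y, None))
                placed += 1
                if placed == n_bg:
                    break

    lma_locs: list[tuple[float, float, str]] = []
    lma_region_counts = {}
    for rid in sorted(regions.regions):
        n = int(rng.poisson(expected[rid]["lma"]))
        lma_region_counts[rid] = n
        for x, y in _uniform_in_polygon(regions.regions[rid], n, rng):
            lma_locs.append((x, y, rid))

    if not pa_pts and not lma_locs:
        raise DegenerateNetworkError(
            "zero PAs and zero LMAs drawn: the network would be empty")

    # --- offshoot grouping: pair nearby PAs onto bifurcated stubs ------
    pts = np.array([(x, y) for x, y, _ in pa_pts]) if pa_pts else np.empty((0, 2))
    used = np.zeros(len(pa_pts), dtype=bool)
    offshoot_groups: list[list[int]] = []   # indices into pa_pts
    for i in range(len(pa_pts)):
        if used[i]:
            continue
        used[i] = True
        pair = None
        if rng.random() < params.offshoot_bifurcation_prob:
            free = np.flatnonzero(~used)
            if free.size:
                d2 = np.sum((pts[free] - pts[i]) ** 2, axis=1)
                j = free[int(np.argmin(d2))]
                if d2.min() < 0.6 ** 2:
                    pair = int(j)
        if pair is not None:
            used[pair] = True
            offshoot_groups.append([i, pair])
        else:
            offshoot_groups.append([i])

    # --- build the angular trunk path ----------------------------------
    nodes: list[NodeRecord] = []
    edges: list[EdgeRecord] = []

    def add_node(nid, p, kind):
        nodes.append(NodeRecord(nid, float(p[0]), float(p[1]), kind))
        return nid

    # hub (stub attachment) per offshoot group
    hub_info = []   # (angle, node_id, position, port_target)
    for g_idx, grp in enumerate(offshoot_groups):
        if len(grp) == 1:
            pa = tuple(pts[grp[0]])
            hub = _toward(pa, cen, 0.12)
        else:
            base = tuple((pts[grp[0]] + pts[grp[1]]) / 2.0)
            hub = _toward(base, cen, 0.20)
        ang = _norm_ang(math.atan2(hub[1] - cen[1], hub[0] - cen[0]))
        hub_info.append((ang, f"h{g_idx}", hub, grp))

    k = len(lma_locs)
    # sort LMAs by angle; sector boundaries between consecutive LMA angles
    lma_order = sorted(range(k), key=lambda i: _norm_ang(
        math.atan2(lma_locs[i][1] - cen[1], lma_locs[i][0] - cen[0])))
    lma_angs = [_norm_ang(math.atan2(lma_locs[i][1] - cen[1],
                                     lma_locs[i][0] - cen[0]))
                for i in lma_order]

    def ellipse_r(ang):
        # radial extent of the slab boundary at this angle
        line_end = (cen[0] + 100 * math.cos(ang), cen[1] + 100 * math.sin(ang))
        inter = slab.exterior.intersection(LineString([cen, line_end]))
        if inter.is_empty:
            return 1.0
        g = inter if inter.geom_type == "Point" else list(inter.geoms)[0]
        return math.dist(cen, (g.x, g.y))

    path_entries = []    # (angle_key, node_id)
    chord_ends = {}      # lma index (sorted order) -> (p_id, q_id)
    if k > 0:
        if k == 1:
            cut = _norm_ang(lma_angs[0] + math.pi)
        else:
            gap = _norm_ang(lma_angs[0] + _TAU - lma_angs[-1])
            cut = _norm_ang(lma_angs[-1] + gap / 2.0)

        def key(ang):       # position along path, from the cut
            return _norm_ang(ang - cut)

        bounds = []         # boundary angle keys between sectors
        for i in range(k - 1):
            bounds.append((key(lma_angs[i]) + key(lma_angs[i + 1])) / 2.0)
        dth = 0.015
        for i in range(k):
            p_key = dth if i == 0 else bounds[i - 1] + dth
            q_key = _TAU - dth if i == k - 1 else bounds[i] + 3 * dth
            # note q_i sits slightly beyond p_{i+1}: chords overlap
            for which, kk in (("p", p_key), ("q", q_key)):
                ang = _norm_ang(cut + kk)
                r = 0.55 * ellipse_r(ang) * rng.uniform(0.92, 1.08)
                pos = (cen[0] + r * math.cos(ang), cen[1] + r * math.sin(ang))
                nid = f"l{which}{i}"
                add_node(nid, pos, "bifurcation")
                path_entries.append((kk, nid))
            chord_ends[i] = (f"lp{i}", f"lq{i}")
        # hubs are clamped into the chord-covered span [p_1, q_k] so every
        # trunk edge lies on some anastomosis cycle (connected backbone)
        lo_key, hi_key = dth + 1e-6, _TAU - dth - 1e-6
        for ang, nid, pos, _ in hub_info:
            add_node(nid, pos, "bifurcation")
            path_entries.append((min(max(key(ang), lo_key), hi_key), nid))
    else:
        for ang, nid, pos, _ in hub_info:
            add_node(nid, pos, "bifurcation")
            path_entries.append((ang, nid))

    pos_of = {n.id: (n.x_mm, n.y_mm) for n in nodes}
    path_entries.sort(key=lambda t: (t[0], t[1]))
    path = [nid for _, nid in path_entries]

    # root near the slab edge before the path start; terminal endpoint after
    first, last = path[0], path[-1]
    root_pos = _toward(pos_of[first], cen, -0.3)
    if not slab.contains(Point(root_pos)):
        root_pos = _toward(pos_of[first], cen, 0.05)
    add_node("root", root_pos, "root")
    end_pos = _toward(pos_of[last], cen, 0.25)
    add_node("end", end_pos, "endpoint")
    pos_of["root"], pos_of["end"] = root_pos, end_pos

    # --- departure ports ------------------------------------------------
    # neighbour lists along the trunk
    nbr: dict[str, list[str]] = {nid: [] for nid in path}
    nbr[path[0]].append("root")
    for a, b in zip(path, path[1:]):
        nbr[a].append(b)
        nbr[b].append(a)
    nbr[path[-1]].append("end")

    chord_end_ids = {pid for pe in chord_ends.values() for pid in pe}
    ports: dict[tuple[str, str], float] = {}   # (node, neighbour/slot) -> angle
    lma_of_end = {}
    for i, (pid, qid) in chord_ends.items():
        lma_of_end[pid] = i
        lma_of_end[qid] = i
    for nid in path:
        others = list(nbr[nid])
        if nid in chord_end_ids:
            i = lma_of_end[nid]
            L = lma_locs[lma_order[i]][:2]
            th_c = math.atan2(L[1] - pos_of[nid][1], L[0] - pos_of[nid][0])
            ports[(nid, "#chord")] = th_c
            slots = [th_c + math.radians(75), th_c - math.radians(75)]
        else:
            base = rng.uniform(0.0, _TAU)
            jit = rng.uniform(-math.radians(10), math.radians(10), 3)
            slots = [base + j * _TAU / 3 + jit[j] for j in range(3)]
            # third slot is the stub port
            ports[(nid, "#stub")] = slots.pop(int(rng.integers(0, 3)))
        # match remaining slots to trunk neighbours by desired direction
        desired = []
        for ob in others:
            op = pos_of[ob]
            desired.append(math.atan2(op[1] - pos_of[nid][1],
                                      op[0] - pos_of[nid][0]))
        if len(others) == 1:
            ports[(nid, others[0])] = slots[0]
        else:
            d0 = abs(math.remainder(desired[0] - slots[0], _TAU))
            d1 = abs(math.remainder(desired[0] - slots[1], _TAU))
            order = [0, 1] if d0 <= d1 else [1, 0]
            ports[(nid, others[0])] = slots[order[0]]
            ports[(nid, others[1])] = slots[order[1]]

    def trunk_polyline(a, b):
        pa_, pb_ = pos_of[a], pos_of[b]
        pl = [pa_]
        if (a, b) in ports:
            pl.append(_elbow(pa_, ports[(a, b)]))
        if (b, a) in ports:
            pl.append(_elbow(pb_, ports[(b, a)]))
        pl.append(pb_)
        return pl

    # --- trunk, root and terminal edges ---------------------------------
    trunk_ids = []
    for j, (a, b) in enumerate(zip(path, path[1:])):
        eid = f"t{j}"
        edges.append(EdgeRecord(eid, a, b, "vessel",
                                "MCA", "MCA", trunk_polyline(a, b)))
        trunk_ids.append(eid)
    pl_root = None
    if (path[0], "root") in ports:
        pl_root = [root_pos, _elbow(pos_of[path[0]], ports[(path[0], "root")]),
                   pos_of[path[0]]]
    edges.append(EdgeRecord("e_root", "root", path[0], "vessel",
                            "MCA", "MCA", pl_root))
    pl_end = None
    if (path[-1], "end") in ports:
        pl_end = [pos_of[path[-1]],
                  _elbow(pos_of[path[-1]], ports[(path[-1], "end")]), end_pos]
    edges.append(EdgeRecord("e_end", path[-1], "end", "vessel",
                            "MCA", "MCA", pl_end))

    # --- LMA chords ------------------------------------------------------
    lma_ids = []
    for i in range(k):
        pid, qid = chord_ends[i]
        L = lma_locs[lma_order[i]][:2]
        pl = _route_chord(pos_of[pid], ports[(pid, "#chord")],
                          pos_of[qid], ports[(qid, "#chord")], L)
        t_b = "MCA"
        if rng.random() < params.lma_cross_territory_prob:
            t_b = "ACA" if L[1] >= cen[1] else "PCA"
        eid = f"lma{i}"
        edges.append(EdgeRecord(eid, pid, qid, "lma", "MCA", t_b, pl))
        lma_ids.append(eid)

    # --- PA offshoot stubs ----------------------------------------------
    pa_node_ids = []
    offshoot_members: list[list[str]] = []
    offshoot_attach: list[str] = []
    offshoot_nv: list[int] = []
    for g_idx, grp in enumerate(offshoot_groups):
        hub_id = f"h{g_idx}"
        hub = pos_of[hub_id]
        stub_port = ports.get((hub_id, "#stub"))
        members = []
        if len(grp) == 1:
            pid = f"pa{grp[0]}"
            add_node(pid, tuple(pts[grp[0]]), "pa")
            pl = [hub, _elbow(hub, stub_port), tuple(map(float, pts[grp[0]]))] \
                if stub_port is not None else None
            edges.append(EdgeRecord(f"s{g_idx}", hub_id, pid, "vessel",
                                    "MCA", "MCA", pl))
            pa_node_ids.append(pid)
            members = [pid]
            nv = 1
        else:
            i1, i2 = grp
            base = tuple((pts[i1] + pts[i2]) / 2.0)
            bpos = _toward(base, cen, 0.08)
            bid = f"b{g_idx}"
            add_node(bid, bpos, "bifurcation")
            pl = [hub, _elbow(hub, stub_port), bpos] if stub_port is not None else None
            edges.append(EdgeRecord(f"s{g_idx}", hub_id, bid, "vessel",
                                    "MCA", "MCA", pl))
            for sub, ii in enumerate((i1, i2)):
                pid = f"pa{ii}"
                add_node(pid, tuple(pts[ii]), "pa")
                edges.append(EdgeRecord(f"s{g_idx}_{sub}", bid, pid, "vessel",
                                        "MCA", "MCA", None))
                pa_node_ids.append(pid)
            members = [bid, f"pa{i1}", f"pa{i2}"]
            nv = 3
        offshoot_members.append(members)
        offshoot_attach.append(hub_id)
        offshoot_nv.append(nv)

    # root and terminal stubs are offshoots too (0 vertices each)
    offshoot_members.append(["root"])
    offshoot_attach.append(path[0])
    offshoot_nv.append(0)
    offshoot_members.append(["end"])
    offshoot_attach.append(path[-1])
    offshoot_nv.append(0)

    # order truth offshoots like topology.decompose (by attachment node id)
    order = sorted(range(len(offshoot_attach)),
                   key=lambda i: offshoot_attach[i])
    memberships = {}
    for rank, i in enumerate(order):
        for m in offshoot_members[i]:
            memberships[m] = rank
    truth = GroundTruth(
        lma_edge_ids=set(lma_ids),
        pa_node_ids=set(pa_node_ids),
        per_region_expected_counts=expected,
        u_animal=u,
        backbone_edge_ids=set(trunk_ids) | set(lma_ids) if k > 0 else set(),
        offshoot_memberships=memberships,
        offshoot_vertices=[offshoot_nv[i] for i in order],
        offshoot_attachments=[offshoot_attach[i] for i in order],
        pa_region_counts=pa_region_counts,
        lma_region_counts=lma_region_counts,
    )

    net = PialNetwork(nodes=nodes, edges=edges, slab_id=animal_id,
                      metadata={"animal_id": animal_id, "group": group,
                                "sex": sex, "age_days": str(age_days)})
    sample = AnimalSample(animal_id=animal_id, group=group, sex=sex,
                          age_days=age_days, network=net, regions=regions,
                          truth=truth)
    findings = [f for f in validate_network(net, regions) if f.severity == "error"]
    if findings:   # construction bug guard; not expected
        raise GenerationError("generated network failed validation: "
                              + "; ".join(str(f) for f in findings[:3]))
    return sample


def generate_cohort(params: GeneratorParams) -> list[AnimalSample]:
    """Generate the full cohort: n_sham sham + n_plucked deprived animals,
    sexes alternating (10 F / 9 M at default sizes), ages uniform in the
    configured range, everything reproducible from ``params.seed``."""
    params.validate()
    n = params.n_sham + params.n_plucked
    if n == 0:
        raise GenerationError("empty cohort requested")
    ss = np.random.SeedSequence(params.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n)]
    cohort = []
    for i in range(n):
        rng = streams[i]
        group = "plucked" if i < params.n_plucked else "sham"
        sex = "F" if i % 2 == 0 else "M"
        lo, hi = params.age_range_days
        age = int(rng.integers(int(lo), int(hi) + 1))
        regions = generate_geometry(params, rng)
        cohort.append(generate_animal_network(
            regions, params, group, rng,
            animal_id=f"m{i + 1:02d}", sex=sex, age_days=age))
    return cohort


# ---------------------------------------------------------------------------
# direct count sampling (no geometry) — the same count law as the cohort

def sample_count_table(params: GeneratorParams, flavor: str = "pa",
                       rng: Optional[np.random.Generator] = None) -> CountTable:
    """Draw an animal × region count table directly from the generative
    count process: C ~ Poisson(rate_r · A_r · e^u · m_r), u ~ N(0, σ_u²).

    Regions use the target areas; identical in law to the counts realized
    by the full geometric generator, and far cheaper for calibration
    studies.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_sham + params.n_plucked
    if n == 0:
        raise GenerationError("empty cohort requested")
    records = []
    lo, hi = params.age_range_days
    for i in range(n):
        group = "plucked" if i < params.n_plucked else "sham"
        sex = "F" if i % 2 == 0 else "M"
        age = int(rng.integers(int(lo), int(hi) + 1))
        u = float(rng.normal(0.0, params.sigma_u)) if params.sigma_u > 0 else 0.0
        for rid in sorted(params.region_areas_mm2):
            area = params.region_areas_mm2[rid]
            if flavor == "pa":
                rate = params.lambda_pa_per_mm2
            elif flavor == "lma":
                rate = params.lma_rate_per_mm2.get(rid, 0.0)
            else:
                raise ValueError(f"unsupported flavor {flavor!r}")
            m = (params.deprivation_multiplier
                 if (group == "plucked" and rid == "barrels") else 1.0)
            c = int(rng.poisson(rate * area * math.exp(u) * m))
            records.append(dict(animal_id=f"m{i + 1:02d}", group=group,
                                sex=sex, age_days=age, region=rid,
                                area_mm2=area, count=c))
    return CountTable.from_records(records, flavor)


# ---------------------------------------------------------------------------
# cohort export

def export_cohort(cohort: list[AnimalSample], out_dir) -> None:
    """Write per-animal GraphML + GeoJSON, a cohort manifest and a truth
    table (CSV) under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    man_rows = []
    truth_rows = []
    for s in cohort:
        gpath = os.path.join(out_dir, f"{s.animal_id}.graphml")
        rpath = os.path.join(out_dir, f"{s.animal_id}.geojson")
        write_network(s.network, gpath)
        write_regions(s.regions, rpath)
        man_rows.append([s.animal_id, s.group, s.sex, s.age_days,
                         os.path.basename(gpath), os.path.basename(rpath)])
        for rid in sorted(s.truth.per_region_expected_counts):
            exp = s.truth.per_region_expected_counts[rid]
            truth_rows.append([
                s.animal_id, rid, f"{s.truth.u_animal:.10g}",
                f"{exp['pa']:.10g}", f"{exp['lma']:.10g}",
                s.truth.pa_region_counts[rid], s.truth.lma_region_counts[rid]])
    with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "group", "sex", "age_days",
                    "network_file", "regions_file"])
        w.writerows(man_rows)
    with open(os.path.join(out_dir, "truth.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["animal_id", "region", "u_animal", "expected_pa",
                    "expected_lma", "n_pa", "n_lma"])
        w.writerows(truth_rows)
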