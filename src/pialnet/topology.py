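"""Structural quantification of pial arterial networks.

The pial network decomposes into a *backbone* — the loop-bearing core
formed by leptomeningeal anastomoses (LMAs) and the vessel paths they
close — and *offshoots*, short bridge subtrees that leave the backbone and
terminate in penetrating arterioles (PAs).  Formally the backbone is the
bridgeless core: the union of all edges lying on at least one cycle.

Offshoot size is summarized by the number of vertices per offshoot, where
a vertex is a bifurcation or a penetrating-arteriole site.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import networkx as nx
from shapely.geometry import Point

from .errors import NoBackboneError
from .netcore import PialNetwork, RegionMap


@dataclass
class Offshoot:
    """One bridge subtree hanging off the backbone."""

    attachment_node: str
    member_node_ids: set[str]
    member_edge_ids: set[str]
    n_vertices: int


@dataclass
class OffshootDecomposition:
    backbone_edge_ids: set[str]
    offshoots: list[Offshoot]

    @property
    def vertices_per_offshoot(self) -> list[int]:
        return [o.n_vertices for o in self.offshoots]


def _bridge_edge_ids(net: PialNetwork) -> set[str]:
    """Edge ids of all bridges, multi-edge aware.

    A parallel pair is never a bridge; a unique edge between two nodes is a
    bridge iff it is one in the simple projection of the graph.
    """
    g = net.to_multigraph()
    simple = nx.Graph()
    mult: dict[frozenset, list[str]] = {}
    for e in net.edges:
        pair = frozenset((e.node_a, e.node_b))
        mult.setdefault(pair, []).append(e.id)
        simple.add_edge(e.node_a, e.node_b)
    simple.add_nodes_from(g.nodes)
    simple_bridges = {frozenset(b) for b in nx.bridges(simple)}
    out = set()
    for pair, ids in mult.items():
        if len(ids) == 1 and pair in simple_bridges:
            out.add(ids[0])
    return out


def loop_count(net: PialNetwork) -> int:
    """Number of independent loops: E − V + number of components."""
    g = net.to_multigraph()
    return (g.number_of_edges() - g.number_of_nodes()
            + nx.number_connected_components(g))


def decompose(net: PialNetwork) -> OffshootDecomposition:
    """Split a network into its bridgeless backbone and bridge offshoots.

    Each maximal bridge subtree hanging off a single backbone node is one
    offshoot; its vertex count is the number of bifurcation or pa nodes
    among its members, the attachment node included only when it is itself
    a pa.  A pa node sitting directly on the backbone with no hanging
    subtree is reported as a zero-length offshoot of one vertex.

    Raises :class:`NoBackboneError` on an acyclic network.
    """
    bridges = _bridge_edge_ids(net)
    backbone = {e.id for e in net.edges} - bridges
    if not backbone:
        raise NoBackboneError(
            "network is acyclic (no anastomosis loops): no backbone exists")

    kinds = {n.id: n.kind for n in net.nodes}
    backbone_nodes: set[str] = set()
    for e in net.edges:
        if e.id in backbone:
            backbone_nodes.add(e.node_a)
            backbone_nodes.add(e.node_b)

    # forest of bridge edges
    forest = nx.MultiGraph()
    forest.add_nodes_from(kinds)
    for e in net.edges:
        if e.id in bridges:
            forest.add_edge(e.node_a, e.node_b, key=e.id)

    offshoots: list[Offshoot] = []
    claimed_backbone_pas: set[str] = set()
    for comp in nx.connected_components(forest):
        comp_edges = {k for _, _, k in forest.subgraph(comp).edges(keys=True)}
        if not comp_edges:
            continue
        attach = sorted(comp & backbone_nodes)
        if not attach:
            # cannot occur on a connected network with a non-empty backbone
            continue
        a = attach[0]
        members = set(comp) - {a}
        # bridge chains between two backbone nodes: treat remaining
        # attachment points as ordinary members of this subtree
        nv = sum(1 for m in members if kinds[m] in ("bifurcation", "pa"))
        if kinds[a] == "pa":
            nv += 1
            claimed_backbone_pas.add(a)
        offshoots.append(Offshoot(a, members, comp_edges, nv))

    # pa nodes on the backbone with nothing hanging off them
    for nid in sorted(backbone_nodes):
        if kinds[nid] == "pa" and nid not in claimed_backbone_pas:
            offshoots.append(Offshoot(nid, set(), set(), 1))

    offshoots.sort(key=lambda o: o.attachment_node)
    return OffshootDecomposition(backbone_edge_ids=backbone, offshoots=offshoots)


# ---------------------------------------------------------------------------
# LMA identification

def _edge_tangent(net_nodes, edge, at: str) -> tuple[float, float]:
    """Unit departure direction of an edge at one of its endpoints.

    Uses the first polyline segment when a polyline is present (the traced
    vessel's local tangent); falls back to the straight chord direction.
    """
    if edge.polyline is not None and len(edge.polyline) >= 2:
        if at == edge.node_a:
            (x0, y0), (x1, y1) = edge.polyline[0], edge.polyline[1]
        else:
            (x0, y0), (x1, y1) = edge.polyline[-1], edge.polyline[-2]
    else:
        a, b = net_nodes[edge.node_a], net_nodes[edge.node_b]
        if at == edge.node_a:
            (x0, y0), (x1, y1) = (a.x_mm, a.y_mm), (b.x_mm, b.y_mm)
        else:
            (x0, y0), (x1, y1) = (b.x_mm, b.y_mm), (a.x_mm, a.y_mm)
    dx, dy = x1 - x0, y1 - y0
    n = math.hypot(dx, dy)
    if n < 1e-12:
        return (0.0, 0.0)
    return (dx / n, dy / n)


def _acute_angle_points_along(net_nodes, incident, edge, at: str) -> bool:
    """True if the bifurcation's acute-angle bisector at ``at`` points
    within 90° of the candidate edge's departure direction.

    The bisector is the normalized vector sum of the departure directions
    of the *other* incident edges; a pass-through junction whose other
    branches are antiparallel has no acute angle and fails.
    """
    ex, ey = _edge_tangent(net_nodes, edge, at)
    sx = sy = 0.0
    for other in incident:
        if other.id == edge.id:
            continue
        ox, oy = _edge_tangent(net_nodes, other, at)
        sx += ox
        sy += oy
    if math.hypot(sx, sy) < 1e-9:
        return False
    return sx * ex + sy * ey > 0.0


def identify_lma_edges(net: PialNetwork, mode: str = "labels") -> set[str]:
    """Identify leptomeningeal-anastomosis edges.

    ``mode="labels"`` trusts the curated ``kind="lma"`` annotations.
    ``mode="geometric"`` applies the morphological criterion: an LMA is a
    loop edge (never a bridge) joining two bifurcations whose acute
    branching angles point towards each other — at each endpoint the
    bisector of the other two branches makes an angle < 90° with the
    departure direction of the candidate edge.
    """
    if mode == "labels":
        return {e.id for e in net.edges if e.kind == "lma"}
    if mode != "geometric":
        raise ValueError(f"unknown mode {mode!r}")

    kinds = {n.id: n.kind for n in net.nodes}
    if not any(k == "bifurcation" for k in kinds.values()):
        warnings.warn("network has no bifurcation nodes; "
                      "geometric LMA identification returns nothing")
        return set()
    nodes = net.node_map()
    incident: dict[str, list] = {n.id: [] for n in net.nodes}
    for e in net.edges:
        incident[e.node_a].append(e)
        incident[e.node_b].append(e)

    bridges = _bridge_edge_ids(net)
    out = set()
    for e in net.edges:
        if e.id in bridges:
            continue
        if kinds[e.node_a] != "bifurcation" or kinds[e.node_b] != "bifurcation":
            continue
        if (_acute_angle_points_along(nodes, incident[e.node_a], e, e.node_a)
                and _acute_angle_points_along(nodes, incident[e.node_b], e, e.node_b)):
            out.add(e.id)
    return out


# ---------------------------------------------------------------------------
# per-region offshoot summary

@dataclass
class RegionRatio:
    region: str
    n_offshoots: int
    n_vertices: int
    ratio: float          # nan when undefined
    defined: bool


def vertex_offshoot_ratio(dec: OffshootDecomposition,
                          region_of: Callable[[int], Optional[str]],
                          regions: Optional[list[str]] = None,
                          ) -> dict[str, RegionRatio]:
    """Mean vertices per offshoot, per cortical region.

    ``region_of(i)`` maps offshoot index ``i`` to a region id or ``None``
    (offshoots outside every region are excluded).  Regions listed in
    ``regions`` but receiving no offshoot are reported as undefined.
    """
    sums: dict[str, list[int]] = {}
    for i, off in enumerate(dec.offshoots):
        r = region_of(i)
        if r is None:
            continue
        s = sums.setdefault(r, [0, 0])
        s[0] += off.n_vertices
        s[1] += 1
    all_regions = set(sums) | set(regions or [])
    out = {}
    for r in sorted(all_regions):
        nv, no = sums.get(r, [0, 0])
        if no == 0:
            out[r] = RegionRatio(r, 0, 0, float("nan"), False)
        else:
            out[r] = RegionRatio(r, no, nv, nv / no, True)
    return out


# ---------------------------------------------------------------------------
# watershed line

def edge_midpoint(net: PialNetwork, edge) -> tuple[float, float]:
    """Arc-length midpoint of an edge's polyline (segment midpoint if none)."""
    nodes = net.node_map()
    if edge.polyline is None or len(edge.polyline) < 2:
        a, b = nodes[edge.node_a], nodes[edge.node_b]
        return ((a.x_mm + b.x_mm) / 2.0, (a.y_mm + b.y_mm) / 2.0)
    pts = edge.polyline
    seg = [math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]
    total = sum(seg)
    if total < 1e-15:
        return pts[0]
    half = total / 2.0
    acc = 0.0
    for i, s in enumerate(seg):
        if acc + s >= half:
            t = (half - acc) / s if s > 0 else 0.0
            (x0, y0), (x1, y1) = pts[i], pts[i + 1]
            return (x0 + t * (x1 - x0), y0 + t * (y1 - y0))
        acc += s
    return pts[-1]


def watershed_polyline(net: PialNetwork,
                       rm: Optional[RegionMap] = None) -> list[tuple[float, float]]:
    """Watershed line between major arterial territories.

    Bisects every LMA whose two ends belong to different territories
    (MCA vs ACA/PCA) and orders the midpoints by angular position about
    the slab centroid (node-coordinate centroid if no RegionMap given).
    """
    cross = [e for e in net.edges
             if e.kind == "lma" and e.territory_a != e.territory_b]
    if not cross:
        warnings.warn("no inter-territory LMAs: watershed line is empty")
        return []
    mids = [edge_midpoint(net, e) for e in cross]
    if rm is not None:
        c = rm.slab.centroid
        cx, cy = c.x, c.y
    else:
        cx = sum(n.x_mm for n in net.nodes) / len(net.nodes)
        cy = sum(n.y_mm for n in net.nodes) / len(net.nodes)
    mids.sort(key=lambda p: math.atan2(p[1] - cy, p[0] - cx))
    return mids


def attachment_region(dec: OffshootDecomposition, net: PialNetwork,
                      rm: RegionMap) -> Callable[[int], Optional[str]]:
    """Region assignment for offshoots: the region containing the
    attachment node (None when the attachment lies outside every region)."""
    nodes = net.node_map()

    def region_of(i: int) -> Optional[str]:
        a = nodes[dec.offshoots[i].attachment_node]
        p = Point(a.x_mm, a.y_mm)
        for rid in sorted(rm.regions):
            if rm.regions[rid].covers(p):
                return rid
        return None

    return region_of
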