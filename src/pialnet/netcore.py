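"""Domain types and I/O for pial arterial networks.

A pial arterial network is a connected planar multigraph traced on the
flattened cortical surface: nodes are bifurcations, penetrating-arteriole
(PA) diving sites, free vessel endpoints, or the root where the middle
cerebral artery enters the slab; edges are surface vessels, a subset of
which are leptomeningeal anastomoses (LMAs) — loop-forming collaterals.
Geometry is planar Cartesian millimetres.

Networks are stored as GraphML (node attrs ``x_mm``, ``y_mm``, ``kind``;
edge attrs ``kind``, ``territory_a``, ``territory_b`` and an optional
``polyline`` of semicolon-separated ``x,y`` pairs).  Region geometry — the
slab outline and up to five primary sensory region polygons — is stored as
a GeoJSON FeatureCollection.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
from shapely.geometry import Point, Polygon, mapping, shape

from .errors import FormatError, ValidationError

#: Fixed vocabulary of primary sensory regions.
REGION_IDS = ("auditory", "barrels", "forelimb", "hindlimb", "visual")

NODE_KINDS = ("bifurcation", "pa", "endpoint", "root")
EDGE_KINDS = ("vessel", "lma")
TERRITORIES = ("MCA", "ACA", "PCA", "unknown")


@dataclass
class NodeRecord:
    """A traced vertex of the pial network (coordinates in mm)."""

    id: str
    x_mm: float
    y_mm: float
    kind: str
    extra: dict = field(default_factory=dict)


@dataclass
class EdgeRecord:
    """A traced vessel segment joining two nodes.

    ``kind="lma"`` is a curated ground-truth label; whether an edge lies on
    a structural cycle is always computed, never trusted from storage, for
    real tracings.  ``polyline``, when present, traces the vessel path and
    must start at ``node_a``'s coordinates and end at ``node_b``'s.
    """

    id: str
    node_a: str
    node_b: str
    kind: str = "vessel"
    territory_a: str = "unknown"
    territory_b: str = "unknown"
    polyline: Optional[list[tuple[float, float]]] = None
    extra: dict = field(default_factory=dict)


@dataclass
class PialNetwork:
    """A connected planar multigraph of pial surface arteries."""

    nodes: list[NodeRecord]
    edges: list[EdgeRecord]
    slab_id: str = ""
    metadata: dict = field(default_factory=dict)

    def node_map(self) -> dict[str, NodeRecord]:
        return {n.id: n for n in self.nodes}

    def to_multigraph(self) -> nx.MultiGraph:
        """Materialize as a networkx MultiGraph (edge key = edge id)."""
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, x_mm=n.x_mm, y_mm=n.y_mm, kind=n.kind)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, key=e.id, kind=e.kind,
                       territory_a=e.territory_a, territory_b=e.territory_b,
                       polyline=e.polyline)
        return g

    def degrees(self) -> dict[str, int]:
        deg = {n.id: 0 for n in self.nodes}
        for e in self.edges:
            for end in (e.node_a, e.node_b):
                if end in deg:   # dangling refs are reported by validation
                    deg[end] += 1
        return deg

    def lma_edges(self) -> list[EdgeRecord]:
        return [e for e in self.edges if e.kind == "lma"]

    def pa_nodes(self) -> list[NodeRecord]:
        return [n for n in self.nodes if n.kind == "pa"]


@dataclass
class RegionMap:
    """The slab outline plus named, non-overlapping sensory region polygons."""

    slab: Polygon
    regions: dict[str, Polygon]

    @property
    def areas(self) -> dict[str, float]:
        """Region areas in mm² (key ``slab`` for the slab itself)."""
        out = {"slab": self.slab.area}
        for rid, poly in self.regions.items():
            out[rid] = poly.area
        return out


@dataclass
class Finding:
    """One validation finding: a violated invariant on a named element."""

    severity: str   # "error" | "warning"
    element: str    # node/edge/region id, or "graph"
    rule: str       # short machine-readable rule name
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.rule} on {self.element}: {self.message}"


# ---------------------------------------------------------------------------
# validation

def validate_network(net: PialNetwork, rm: Optional[RegionMap] = None) -> list[Finding]:
    """Check every structural invariant; return findings (empty = valid).

    Checks: unique node ids, edges referencing two existing distinct nodes,
    connectivity, kind/degree consistency (bifurcation ⇒ degree ≥ 3,
    endpoint ⇒ degree 1, pa ⇒ degree ≥ 1), polyline endpoint agreement, and
    — when a RegionMap is given — every node inside or on the slab.
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    for n in net.nodes:
        if n.id in seen:
            findings.append(Finding("error", n.id, "duplicate-node-id",
                                    f"node id {n.id!r} occurs more than once"))
        seen.add(n.id)
        if n.kind not in NODE_KINDS:
            findings.append(Finding("error", n.id, "unknown-node-kind",
                                    f"kind {n.kind!r} not in {NODE_KINDS}"))
    if not net.nodes:
        findings.append(Finding("error", "graph", "empty-graph", "network has no nodes"))
        return findings

    nodes = net.node_map()
    for e in net.edges:
        if e.node_a == e.node_b:
            findings.append(Finding("error", e.id, "self-loop",
                                    f"edge {e.id!r} joins node {e.node_a!r} to itself"))
        for end in (e.node_a, e.node_b):
            if end not in nodes:
                findings.append(Finding("error", e.id, "dangling-edge",
                                        f"edge {e.id!r} references missing node {end!r}"))
        if e.kind not in EDGE_KINDS:
            findings.append(Finding("error", e.id, "unknown-edge-kind",
                                    f"kind {e.kind!r} not in {EDGE_KINDS}"))
        if e.polyline is not None and e.node_a in nodes and e.node_b in nodes:
            a, b = nodes[e.node_a], nodes[e.node_b]
            pl = e.polyline
            if (len(pl) < 2
                    or math.dist(pl[0], (a.x_mm, a.y_mm)) > 1e-9
                    or math.dist(pl[-1], (b.x_mm, b.y_mm)) > 1e-9):
                findings.append(Finding("error", e.id, "polyline-endpoints",
                                        f"polyline of edge {e.id!r} does not run "
                                        f"from node_a to node_b coordinates"))

    deg = net.degrees()
    for n in net.nodes:
        d = deg[n.id]
        if n.kind == "bifurcation" and d < 3:
            findings.append(Finding("error", n.id, "bifurcation-degree",
                                    f"bifurcation node {n.id!r} has degree {d} < 3"))
        elif n.kind == "endpoint" and d != 1:
            findings.append(Finding("error", n.id, "endpoint-degree",
                                    f"endpoint node {n.id!r} has degree {d} != 1"))
        elif n.kind == "pa" and d < 1:
            findings.append(Finding("error", n.id, "pa-degree",
                                    f"pa node {n.id!r} is isolated"))

    g = net.to_multigraph()
    if g.number_of_nodes() and not nx.is_connected(g):
        findings.append(Finding("error", "graph", "disconnected",
                                f"network has {nx.number_connected_components(g)} "
                                f"components; expected 1"))

    if rm is not None:
        slab = rm.slab.buffer(1e-9)  # tolerate on-boundary points
        for n in net.nodes:
            if not slab.contains(Point(n.x_mm, n.y_mm)):
                findings.append(Finding("error", n.id, "node-outside-slab",
                                        f"node {n.id!r} at ({n.x_mm}, {n.y_mm}) "
                                        f"lies outside the slab polygon"))
    return findings


def _require_valid(net: PialNetwork, rm: Optional[RegionMap] = None) -> None:
    findings = [f for f in validate_network(net, rm) if f.severity == "error"]
    if findings:
        raise ValidationError("; ".join(str(f) for f in findings[:5]))


# ---------------------------------------------------------------------------
# GraphML I/O

_NODE_KEYS = (("x_mm", "double"), ("y_mm", "double"), ("kind", "string"))
_EDGE_KEYS = (("kind", "string"), ("territory_a", "string"),
              ("territory_b", "string"), ("polyline", "string"))
_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def _fmt(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def polyline_to_str(pl: Iterable[tuple[float, float]]) -> str:
    return ";".join(f"{_fmt(float(x))},{_fmt(float(y))}" for x, y in pl)


def polyline_from_str(s: str) -> list[tuple[float, float]]:
    pts = []
    for tok in s.split(";"):
        x, y = tok.split(",")
        pts.append((float(x), float(y)))
    return pts


def write_network(net: PialNetwork, path) -> None:
    """Write GraphML with a canonical, byte-stable layout.

    Nodes and edges are sorted by id and attributes emitted in a fixed
    order with ``repr``-formatted (locale-independent) floats, so writing
    the same network twice yields identical bytes.  The network is
    validated before anything is written.
    """
    _require_valid(net)
    root = ET.Element("graphml", xmlns=_GRAPHML_NS)
    keyid = {}
    i = 0

    def declare(domain, name, atype):
        nonlocal i
        k = ET.SubElement(root, "key", id=f"d{i}")
        k.set("for", domain)
        k.set("attr.name", name)
        k.set("attr.type", atype)
        keyid[(domain, name)] = f"d{i}"
        i += 1

    extra_node = sorted({k for n in net.nodes for k in n.extra})
    extra_edge = sorted({k for e in net.edges for k in e.extra})
    meta_keys = sorted(net.metadata)
    for name, atype in _NODE_KEYS:
        declare("node", name, atype)
    for name in extra_node:
        declare("node", name, "string")
    for name, atype in _EDGE_KEYS:
        declare("edge", name, atype)
    for name in extra_edge:
        declare("edge", name, "string")
    declare("graph", "slab_id", "string")
    for name in meta_keys:
        declare("graph", name, "string")

    graph = ET.SubElement(root, "graph", id="G", edgedefault="undirected")

    def data(parent, domain, name, value):
        d = ET.SubElement(parent, "data", key=keyid[(domain, name)])
        d.text = _fmt(value)

    data(graph, "graph", "slab_id", net.slab_id)
    for name in meta_keys:
        data(graph, "graph", name, net.metadata[name])
    for n in sorted(net.nodes, key=lambda n: n.id):
        el = ET.SubElement(graph, "node", id=n.id)
        data(el, "node", "x_mm", float(n.x_mm))
        data(el, "node", "y_mm", float(n.y_mm))
        data(el, "node", "kind", n.kind)
        for k in sorted(n.extra):
            data(el, "node", k, n.extra[k])
    for e in sorted(net.edges, key=lambda e: e.id):
        el = ET.SubElement(graph, "edge", id=e.id, source=e.node_a, target=e.node_b)
        data(el, "edge", "kind", e.kind)
        data(el, "edge", "territory_a", e.territory_a)
        data(el, "edge", "territory_b", e.territory_b)
        if e.polyline is not None:
            data(el, "edge", "polyline", polyline_to_str(e.polyline))
        for k in sorted(e.extra):
            data(el, "edge", k, e.extra[k])

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="utf-8", xml_declaration=True)


_KNOWN_NODE = {"x_mm", "y_mm", "kind"}
_KNOWN_EDGE = {"kind", "territory_a", "territory_b", "polyline"}


def read_network(path, format: str = "graphml") -> PialNetwork:
    """Read and validate a GraphML network file.

    Unknown node/edge attributes are preserved verbatim in each record's
    ``extra`` mapping; unknown graph-level attributes go to ``metadata``.
    """
    if format != "graphml":
        raise FormatError(f"unsupported format {format!r}")
    try:
        g = nx.read_graphml(path, force_multigraph=True)
    except Exception as exc:  # malformed XML etc.
        raise FormatError(f"could not parse GraphML file {path}: {exc}") from exc

    nodes = []
    for nid, attrs in g.nodes(data=True):
        for req in ("x_mm", "y_mm", "kind"):
            if req not in attrs:
                raise FormatError(f"node {nid!r} lacks required attribute {req!r}")
        extra = {k: v for k, v in attrs.items() if k not in _KNOWN_NODE}
        nodes.append(NodeRecord(id=str(nid), x_mm=float(attrs["x_mm"]),
                                y_mm=float(attrs["y_mm"]), kind=str(attrs["kind"]),
                                extra=extra))
    edges = []
    for u, v, key, attrs in g.edges(keys=True, data=True):
        if "kind" not in attrs:
            raise FormatError(f"edge {key!r} ({u!r}–{v!r}) lacks required attribute 'kind'")
        pl = attrs.get("polyline")
        extra = {k: v for k, v in attrs.items() if k not in _KNOWN_EDGE and k != "id"}
        edges.append(EdgeRecord(
            id=str(attrs.get("id", key)), node_a=str(u), node_b=str(v),
            kind=str(attrs["kind"]),
            territory_a=str(attrs.get("territory_a", "unknown")),
            territory_b=str(attrs.get("territory_b", "unknown")),
            polyline=polyline_from_str(pl) if pl else None,
            extra=extra))
    gattrs = dict(g.graph)
    gattrs.pop("node_default", None)
    gattrs.pop("edge_default", None)
    slab_id = str(gattrs.pop("slab_id", ""))
    net = PialNetwork(nodes=nodes, edges=edges, slab_id=slab_id, metadata=gattrs)
    _restore_edge_orientation(net, path)
    _require_valid(net)
    return net


def _restore_edge_orientation(net: PialNetwork, path) -> None:
    """Re-anchor edge records to the stored source/target order.

    networkx's undirected GraphML reader does not preserve endpoint
    order, but ``territory_a``/``territory_b`` and the polyline direction
    are defined relative to ``node_a``; recover the order from the XML.
    """
    stored: dict[str, tuple[str, str]] = {}
    try:
        for _, el in ET.iterparse(path, events=("end",)):
            if el.tag.endswith("edge"):
                eid = el.get("id")
                if eid is not None:
                    stored[eid] = (el.get("source"), el.get("target"))
                el.clear()
    except ET.ParseError:
        return
    # attribute values (territories, polyline) are anchored to the stored
    # source node, so only the endpoint order needs restoring
    for e in net.edges:
        st = stored.get(e.id)
        if st == (e.node_b, e.node_a):
            e.node_a, e.node_b = st


# ---------------------------------------------------------------------------
# GeoJSON region I/O

def write_regions(rm: RegionMap, path) -> None:
    """Write the slab + regions as a GeoJSON FeatureCollection (byte-stable)."""
    _validate_regions(rm)
    feats = [{
        "type": "Feature",
        "properties": {"role": "slab"},
        "geometry": mapping(rm.slab),
    }]
    for rid in sorted(rm.regions):
        feats.append({
            "type": "Feature",
            "properties": {"role": "region", "region_id": rid,
                           "area_mm2": rm.regions[rid].area},
            "geometry": mapping(rm.regions[rid]),
        })
    doc = {"type": "FeatureCollection", "features": feats}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_regions(path) -> RegionMap:
    """Read a GeoJSON FeatureCollection with one slab and ≤5 region features."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    slab = None
    regions: dict[str, Polygon] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if props.get("role") == "slab":
            if slab is not None:
                raise FormatError("multiple slab features")
            slab = geom
        else:
            rid = props.get("region_id")
            if rid not in REGION_IDS:
                raise FormatError(f"unknown region_id {rid!r}")
            if rid in regions:
                raise FormatError(f"duplicate region_id {rid!r}")
            regions[rid] = geom
            stored = props.get("area_mm2")
            if stored is not None and abs(stored - geom.area) > 1e-9 * max(1.0, geom.area):
                raise ValidationError(
                    f"stored area of region {rid!r} ({stored}) disagrees with "
                    f"computed polygon area ({geom.area})")
    if slab is None:
        raise FormatError("no slab feature (role='slab') found")
    rm = RegionMap(slab=slab, regions=regions)
    _validate_regions(rm)
    return rm


def _validate_regions(rm: RegionMap) -> None:
    if not rm.slab.is_valid or rm.slab.is_empty:
        raise ValidationError("slab polygon is invalid or empty")
    ids = sorted(rm.regions)
    for rid in ids:
        poly = rm.regions[rid]
        if not poly.is_valid:
            raise ValidationError(f"region {rid!r} polygon is self-intersecting")
        if poly.difference(rm.slab.buffer(1e-9)).area > 1e-9:
            raise ValidationError(f"region {rid!r} is not contained in the slab")
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            inter = rm.regions[a].intersection(rm.regions[b]).area
            if inter >= 1e-9:
                raise ValidationError(
                    f"regions {a!r} and {b!r} overlap by {inter:.3g} mm²")
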