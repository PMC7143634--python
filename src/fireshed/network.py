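"""Street-network graph model.

The street network is an undirected planar graph ``G = (V, E)`` whose edges
carry metric polyline geometry (coordinates in a projected CRS, metres).
Facility points ("generators") and incident points live off-network and are
projected onto their Euclidean-nearest location on an edge before any network
computation.

All ids are deterministic: nodes are numbered in discovery order, edges in
input order, and every split (station insertion, lixel densification) assigns
fresh ids from a monotone counter, so identical inputs yield identical graphs.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import shapely
from shapely.geometry import LineString, Point
from shapely.ops import substring

logger = logging.getLogger(__name__)

#: Euclidean tolerance (metres) below which two locations are the same point.
GEOM_TOL = 1e-6


@dataclass(frozen=True)
class NetworkLocation:
    """A point on the network: an edge id plus an arc-length offset (metres)
    measured from the edge's first endpoint."""

    edge_id: int
    offset: float


@dataclass
class Edge:
    edge_id: int
    u: int
    v: int
    geom: LineString
    length: float
    parent: int | None = None


@dataclass
class Station:
    """A facility (generator) with its raw location, its projection onto the
    network, and the graph node anchoring its expansion operator."""

    station_id: int
    raw: tuple[float, float]
    projected: NetworkLocation
    projection_distance: float
    anchor: int


class NetGraph:
    """Undirected street graph with metric edge geometry.

    Mutating operations (:func:`insert_station`, :func:`densify`) modify the
    graph in place and return it for chaining.
    """

    def __init__(self) -> None:
        self.nodes: dict[int, tuple[float, float]] = {}
        self.edges: dict[int, Edge] = {}
        self.densified: bool = False
        self.lixel_size: float | None = None
        self._adj: dict[int, list[tuple[int, int]]] = {}
        self._next_node = 0
        self._next_edge = 0
        self._version = 0
        self._geom_cache: tuple[int, list[int], np.ndarray] | None = None

    # -- construction ------------------------------------------------------

    def add_node(self, x: float, y: float) -> int:
        nid = self._next_node
        self._next_node += 1
        self.nodes[nid] = (float(x), float(y))
        self._adj[nid] = []
        self._version += 1
        return nid

    def add_edge(self, u: int, v: int, geom: LineString,
                 parent: int | None = None) -> int:
        eid = self._next_edge
        self._next_edge += 1
        e = Edge(eid, u, v, geom, float(geom.length), parent)
        self.edges[eid] = e
        self._adj[u].append((eid, v))
        if v != u:
            self._adj[v].append((eid, u))
        self._version += 1
        return eid

    def remove_edge(self, eid: int) -> None:
        e = self.edges.pop(eid)
        self._adj[e.u] = [p for p in self._adj[e.u] if p[0] != eid]
        if e.v != e.u:
            self._adj[e.v] = [p for p in self._adj[e.v] if p[0] != eid]
        self._version += 1

    def neighbors(self, node: int) -> list[tuple[int, int]]:
        """(edge_id, other_endpoint) pairs incident to ``node``."""
        return self._adj[node]

    @property
    def total_length(self) -> float:
        return sum(e.length for e in self.edges.values())

    def degree(self, node: int) -> int:
        return len(self._adj[node])

    def components(self) -> list[set[int]]:
        """Connected components as sets of node ids (deterministic order)."""
        seen: set[int] = set()
        out: list[set[int]] = []
        for start in self.nodes:
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                n = stack.pop()
                for _, other in self._adj[n]:
                    if other not in comp:
                        comp.add(other)
                        stack.append(other)
            seen |= comp
            out.append(comp)
        return out

    def copy(self) -> "NetGraph":
        """Independent copy (geometries are immutable and shared)."""
        g = NetGraph()
        g.nodes = dict(self.nodes)
        g.edges = {eid: Edge(e.edge_id, e.u, e.v, e.geom, e.length, e.parent)
                   for eid, e in self.edges.items()}
        g._adj = {n: list(v) for n, v in self._adj.items()}
        g._next_node = self._next_node
        g._next_edge = self._next_edge
        g.densified = self.densified
        g.lixel_size = self.lixel_size
        return g

    def signature(self) -> tuple[int, int, float]:
        """Cheap identity check used to refuse cross-graph comparisons."""
        return (len(self.nodes), len(self.edges), round(self.total_length, 6))

    # -- geometry queries --------------------------------------------------

    def _edge_geoms(self) -> tuple[list[int], np.ndarray]:
        if self._geom_cache is None or self._geom_cache[0] != self._version:
            ids = sorted(self.edges)
            arr = np.array([self.edges[i].geom for i in ids], dtype=object)
            self._geom_cache = (self._version, ids, arr)
        return self._geom_cache[1], self._geom_cache[2]

    def split_edge(self, eid: int, offset: float) -> tuple[int, int, int]:
        """Split edge ``eid`` at arc-length ``offset``, inserting a new node.

        Returns ``(new_node, first_piece_id, second_piece_id)``. The two
        pieces inherit the original edge as ``parent``.
        """
        e = self.edges[eid]
        if not (GEOM_TOL < offset < e.length - GEOM_TOL):
            raise ValueError(f"split offset {offset} not interior to edge {eid}")
        pt = e.geom.interpolate(offset)
        g1 = substring(e.geom, 0.0, offset)
        g2 = substring(e.geom, offset, e.length)
        self.remove_edge(eid)
        mid = self.add_node(pt.x, pt.y)
        e1 = self.add_edge(e.u, mid, g1, parent=eid)
        e2 = self.add_edge(mid, e.v, g2, parent=eid)
        return mid, e1, e2


# ---------------------------------------------------------------------------


class _SnapIndex:
    """Grid hash for merging endpoints closer than the snap tolerance."""

    def __init__(self, tol: float) -> None:
        self.tol = tol
        self.cell = max(tol, GEOM_TOL)
        self.buckets: dict[tuple[int, int], list[tuple[int, float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(math.floor(x / self.cell)), int(math.floor(y / self.cell)))

    def find(self, x: float, y: float) -> int | None:
        kx, ky = self._key(x, y)
        best: tuple[float, int] | None = None
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for nid, nx_, ny_ in self.buckets.get((kx + dx, ky + dy), ()):
                    d = math.hypot(nx_ - x, ny_ - y)
                    if d <= self.tol and (best is None or (d, nid) < best):
                        best = (d, nid)
        return None if best is None else best[1]

    def add(self, nid: int, x: float, y: float) -> None:
        self.buckets.setdefault(self._key(x, y), []).append((nid, x, y))


def build_topology(line_features: Iterable[LineString],
                   snap_tolerance: float = 0.5) -> NetGraph:
    """Build the street graph from polyline features.

    Each polyline becomes one edge; endpoints closer than ``snap_tolerance``
    (metres) are merged into a single node and the polyline's terminal
    vertices are moved onto the node position. Features whose length collapses
    to zero after snapping are rejected with a warning.
    """
    feats = list(line_features)
    if not feats:
        raise ValueError("no line features supplied")
    g = NetGraph()
    index = _SnapIndex(snap_tolerance)

    def node_for(x: float, y: float) -> int:
        nid = index.find(x, y)
        if nid is None:
            nid = g.add_node(x, y)
            index.add(nid, x, y)
        return nid

    for i, geom in enumerate(feats):
        coords = list(geom.coords)
        if len(coords) < 2:
            logger.warning("feature %d has fewer than 2 vertices; skipped", i)
            continue
        u = node_for(*coords[0][:2])
        v = node_for(*coords[-1][:2])
        coords[0] = g.nodes[u]
        coords[-1] = g.nodes[v]
        snapped = LineString(coords)
        if snapped.length <= GEOM_TOL:
            logger.warning("feature %d collapsed to zero length; skipped", i)
            continue
        g.add_edge(u, v, snapped)
    if not g.edges:
        raise ValueError("all features rejected; empty network")
    ncomp = len(g.components())
    if ncomp > 1:
        logger.info("network has %d connected components", ncomp)
    return g


def project_to_network(p: tuple[float, float],
                       g: NetGraph) -> tuple[NetworkLocation, float]:
    """Euclidean-nearest location on any edge.

    Ties within 1e-9 m are broken by lowest edge id, then lowest offset.
    """
    if not g.edges:
        raise ValueError("empty network")
    ids, geoms = g._edge_geoms()
    pt = Point(p)
    dists = shapely.distance(geoms, pt)
    dmin = float(dists.min())
    best: tuple[int, float] | None = None
    for k in np.flatnonzero(dists <= dmin + 1e-9):
        eid = ids[int(k)]
        off = float(g.edges[eid].geom.project(pt))
        off = min(max(off, 0.0), g.edges[eid].length)
        if best is None or (eid, off) < best:
            best = (eid, off)
    eid, off = best
    return NetworkLocation(eid, off), dmin


def insert_station(g: NetGraph, station_id: int,
                   raw: tuple[float, float]) -> tuple[NetGraph, Station]:
    """Project a facility point onto the network and anchor it at a graph
    node, splitting the host edge at the projection point when it falls in
    the edge interior."""
    loc, dist = project_to_network(raw, g)
    e = g.edges[loc.edge_id]
    if loc.offset <= GEOM_TOL:
        anchor = e.u
    elif loc.offset >= e.length - GEOM_TOL:
        anchor = e.v
    else:
        anchor, _, _ = g.split_edge(loc.edge_id, loc.offset)
    st = Station(station_id, (float(raw[0]), float(raw[1])), loc, dist, anchor)
    return g, st


def densify(g: NetGraph, lixel_size: float) -> NetGraph:
    """Subdivide every edge into lixels of at most ``lixel_size`` metres.

    Cut points sit at multiples of ``lixel_size`` from the edge's first
    endpoint; the final piece carries the remainder. Total length is
    conserved and the operation is idempotent at a fixed lixel size.
    """
    if lixel_size <= 0:
        raise ValueError("lixel_size must be positive")
    for eid in sorted(g.edges):
        e = g.edges[eid]
        n_whole = int(math.floor(e.length / lixel_size))
        rem = e.length - n_whole * lixel_size
        n_pieces = n_whole + (1 if rem > GEOM_TOL else 0)
        if n_pieces <= 1:
            continue
        g.remove_edge(eid)
        prev_node = e.u
        prev_off = 0.0
        for k in range(1, n_pieces):
            off = k * lixel_size
            pt = e.geom.interpolate(off)
            mid = g.add_node(pt.x, pt.y)
            g.add_edge(prev_node, mid, substring(e.geom, prev_off, off),
                       parent=eid)
            prev_node, prev_off = mid, off
        g.add_edge(prev_node, e.v, substring(e.geom, prev_off, e.length),
                   parent=eid)
    g.densified = True
    g.lixel_size = lixel_size
    return g


# ---------------------------------------------------------------------------


def _edge_weight_fn(g: NetGraph, role):
    if role == "length":
        return lambda eid: g.edges[eid].length
    if isinstance(role, Mapping):
        return lambda eid: role[eid]
    raise ValueError("edge_weight_role must be 'length' or a mapping edge->w")


def dijkstra(g: NetGraph, seeds: Iterable[tuple[int, float]],
             weight="length", cutoff: float = math.inf) -> dict[int, float]:
    """Multi-seed Dijkstra returning ``{node: weight}`` for nodes whose best
    cumulative weight is <= cutoff. ``seeds`` are (node, initial_weight)."""
    wfn = _edge_weight_fn(g, weight)
    dist: dict[int, float] = {}
    heap: list[tuple[float, int]] = []
    for node, w0 in seeds:
        if w0 <= cutoff:
            heapq.heappush(heap, (w0, node))
    while heap:
        d, n = heapq.heappop(heap)
        if n in dist:
            continue
        dist[n] = d
        for eid, other in g.neighbors(n):
            if other in dist:
                continue
            nd = d + wfn(eid)
            if nd <= cutoff:
                heapq.heappush(heap, (nd, other))
    return dist


def bounded_network_distance(g: NetGraph, source: int, radius: float,
                             edge_weight_role="length") -> dict[int, float]:
    """Single-source shortest-path weights truncated at ``radius``.

    ``edge_weight_role`` is ``"length"`` (geometric metres) or a mapping
    ``edge_id -> weight`` (e.g. combined length/risk cost).
    """
    if source not in g.nodes:
        raise KeyError(f"source node {source} not in graph")
    if radius <= 0:
        raise ValueError("radius must be positive")
    return dijkstra(g, [(source, 0.0)], edge_weight_role, cutoff=radius)
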