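"""Evaluation machinery: planar baseline, coverage, difference, dynamics.

The planar Thiessen baseline assigns street segments to the Euclidean-nearest
facility, deliberately ignoring the network — it is the 2-D control whose
service areas can fragment into enclaves. Coverage length measures, per
facility, how much of its own territory it can reach within the response
radius without leaving that territory; difference length measures how much
network two partitions assign to different owners.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import GEOM_TOL, NetGraph, Station
from .partition import (CostWeights, EdgeAssignment, NodeAssignment,
                        Partition, PartitionConfig, cvd_partition, edge_costs,
                        nvd_partition, split_boundary_edges)
from .risk import IncidentSet, filter_by_period, nkde, segment_risk


@dataclass
class CoverageReport:
    threshold: float
    per_station_covered: dict[int, float]
    per_station_total: dict[int, float]

    @property
    def total_covered(self) -> float:
        return sum(self.per_station_covered.values())

    @property
    def total_assigned(self) -> float:
        return sum(self.per_station_total.values())


@dataclass
class DifferenceReport:
    total_m: float
    by_region: dict | None = None


def planar_thiessen_partition(stations: list[Station],
                              g: NetGraph) -> Partition:
    """Assign each (densified) edge to the facility whose *raw* location is
    Euclidean-nearest to the edge midpoint — the 2-D Thiessen baseline.

    Connectivity of the resulting territories is not enforced; fragmenting
    into enclaves is exactly what this baseline is meant to expose.
    """
    if not stations:
        raise ValueError("at least one station required")
    sts = sorted(stations, key=lambda s: s.station_id)
    pts = np.array([s.raw for s in sts])
    sids = [s.station_id for s in sts]
    for i in range(len(sts)):
        for j in range(i + 1, len(sts)):
            if math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1]) < GEOM_TOL:
                raise ValueError(
                    f"stations {sids[i]} and {sids[j]} are coincident")

    def nearest(x: float, y: float) -> tuple[int, float]:
        d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
        k = int(np.argmin(d))  # np.argmin takes the first (lowest sid) on ties
        return sids[k], float(d[k])

    nodes: dict[int, NodeAssignment] = {}
    for nid, (x, y) in g.nodes.items():
        sid, d = nearest(x, y)
        nodes[nid] = NodeAssignment(sid, d, d, 1)
    edges: dict[int, EdgeAssignment] = {}
    for eid, e in g.edges.items():
        mid = e.geom.interpolate(0.5, normalized=True)
        sid, _ = nearest(mid.x, mid.y)
        edges[eid] = EdgeAssignment(owner=sid)
    return Partition(nodes=nodes, edges=edges, unassigned_nodes=set(),
                     stations={s.station_id: s for s in sts},
                     graph_signature=g.signature(),
                     meta={"mode": "planar"})


def coverage_length(partition: Partition, g: NetGraph,
                    d_max: float) -> CoverageReport:
    """Per-facility length of its own territory reachable within ``d_max``.

    The sweep runs by geometric length from the facility's anchor and is
    restricted to the edges that facility owns: reaching an enclave through
    another facility's territory does not count, which is precisely the
    continuity argument against the planar baseline. A split edge is
    traversable only up to its break point.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    covered: dict[int, float] = {}
    totals: dict[int, float] = {}
    for sid, st in sorted(partition.stations.items()):
        whole: list[int] = []
        halves: list[tuple[int, float]] = []  # (attach node, length)
        adj: dict[int, list[tuple[float, int]]] = {}
        total = 0.0
        for eid, ea in partition.edges.items():
            e = g.edges[eid]
            if ea.is_split:
                if ea.owner_u == sid:
                    halves.append((e.u, ea.split_offset))
                    total += ea.split_offset
                if ea.owner_v == sid:
                    halves.append((e.v, e.length - ea.split_offset))
                    total += e.length - ea.split_offset
            elif ea.owner == sid:
                whole.append(eid)
                total += e.length
                adj.setdefault(e.u, []).append((e.length, e.v))
                adj.setdefault(e.v, []).append((e.length, e.u))
        totals[sid] = total
        dist: dict[int, float] = {}
        heap = [(0.0, st.anchor)]
        while heap:
            d, n = heapq.heappop(heap)
            if n in dist:
                continue
            dist[n] = d
            for ln, other in adj.get(n, ()):
                if other not in dist:
                    heapq.heappush(heap, (d + ln, other))
        # partial prefixes of edges whose far end lies beyond d_max fall out
        # of the max(0, d_max - d) terms below
        cov = 0.0
        for eid in whole:
            e = g.edges[eid]
            du = dist.get(e.u, math.inf)
            dv = dist.get(e.v, math.inf)
            reach = 0.0
            if math.isfinite(du):
                reach += max(0.0, d_max - du)
            if math.isfinite(dv):
                reach += max(0.0, d_max - dv)
            cov += min(e.length, reach)
        for node, ln in halves:
            dn = dist.get(node, math.inf)
            if math.isfinite(dn):
                cov += min(ln, max(0.0, d_max - dn))
        covered[sid] = cov
    return CoverageReport(d_max, covered, totals)


def _full_intervals(partition: Partition, g: NetGraph
                    ) -> dict[int, list[tuple[float, float, int | None]]]:
    ivs = partition.edge_intervals(g)
    out = {}
    for eid, e in g.edges.items():
        out[eid] = ivs.get(eid, [(0.0, e.length, None)])
    return out


def partition_difference_length(p1: Partition, p2: Partition, g: NetGraph,
                                regions=None) -> DifferenceReport:
    """Total network length assigned to different owners by two partitions.

    Split offsets are resolved onto a common refinement per edge, so the
    measure is symmetric and zero iff the partitions agree everywhere.
    ``regions`` may be a list of (region_id, shapely Polygon); differing
    portions are then also accumulated per region by segment-midpoint
    containment.
    """
    if p1.graph_signature != p2.graph_signature:
        raise ValueError("partitions were computed on different graphs")
    iv1 = _full_intervals(p1, g)
    iv2 = _full_intervals(p2, g)
    total = 0.0
    by_region: dict | None = None
    if regions is not None:
        by_region = {rid: 0.0 for rid, _ in regions}
        by_region["<outside>"] = 0.0
    for eid, e in g.edges.items():
        cuts = sorted({0.0, e.length}
                      | {s for s, _, _ in iv1[eid]} | {t for _, t, _ in iv1[eid]}
                      | {s for s, _, _ in iv2[eid]} | {t for _, t, _ in iv2[eid]})

        def owner_at(ivs, m):
            # intervals always cover [0, length]; m is strictly interior to
            # one refined piece
            for s, t, o in ivs:
                if s <= m < t:
                    return o
            return ivs[-1][2]

        for s, t in zip(cuts[:-1], cuts[1:]):
            if t - s <= GEOM_TOL:
                continue
            m = 0.5 * (s + t)
            o1 = owner_at(iv1[eid], m)
            o2 = owner_at(iv2[eid], m)
            if o1 != o2:
                total += t - s
                if by_region is not None:
                    pt = e.geom.interpolate(m)
                    hit = "<outside>"
                    for rid, poly in regions:
                        if poly.covers(pt):
                            hit = rid
                            break
                    by_region[hit] += t - s
    return DifferenceReport(total, by_region)


def enclave_check(partition: Partition, g: NetGraph) -> dict[int, int]:
    """Connected-component count of each facility's owned edge set.

    1 means a contiguous service area; >= 2 means enclaves exist (a portion
    reachable only through other facilities' territory); 0 an empty area.
    """
    parent: dict[tuple[int, object], tuple[int, object]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        for z in (x, y):
            parent.setdefault(z, z)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    touched: dict[int, set] = {sid: set() for sid in partition.stations}
    for eid, ea in partition.edges.items():
        e = g.edges[eid]
        if ea.is_split:
            for sid, node in ((ea.owner_u, e.u), (ea.owner_v, e.v)):
                key = (sid, node)
                parent.setdefault(key, key)
                touched.setdefault(sid, set()).add(key)
        elif ea.owner is not None:
            sid = ea.owner
            ku, kv = (sid, e.u), (sid, e.v)
            union(ku, kv)
            touched.setdefault(sid, set()).add(ku)
            touched[sid].add(kv)
    return {sid: len({find(k) for k in keys})
            for sid, keys in sorted(touched.items())}


# -- dynamic (time-sliced) runs --------------------------------------------


def monthly_windows(start, months: int) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    """Consecutive half-open calendar-month windows starting at ``start``."""
    start = pd.Timestamp(start).normalize().replace(day=1)
    edges = [start + pd.DateOffset(months=k) for k in range(months + 1)]
    return list(zip(edges[:-1], edges[1:]))


def build_partition(g: NetGraph, stations: list[Station],
                    incidents: IncidentSet,
                    config: PartitionConfig) -> tuple[Partition, CostWeights]:
    """NKDE -> segment risk -> blended costs -> partition -> boundary split."""
    fld = nkde(g, incidents, config.bandwidth)
    risks = segment_risk(fld, g)
    costs = edge_costs(g, risks, config.a)
    if config.mode == "planar":
        part = planar_thiessen_partition(stations, g)
        return part, costs
    fn = cvd_partition if config.mode == "cvd" else nvd_partition
    part = fn(g, stations, costs, config)
    part = split_boundary_edges(part, g, costs)
    return part, costs


@dataclass
class WindowResult:
    window: tuple[pd.Timestamp, pd.Timestamp]
    partition: Partition
    coverage: CoverageReport
    difference_vs_full: DifferenceReport
    service_lengths: dict[int, float]
    n_incidents: int


def dynamic_run(g: NetGraph, stations: list[Station], incidents: IncidentSet,
                windows, config: PartitionConfig,
                full_partition: Partition | None = None) -> list[WindowResult]:
    """One partition per time window using only that window's incidents,
    compared against the all-data partition.

    An empty window falls back to pure length costs (zero risk everywhere),
    which is a valid partition, not an error.
    """
    for (s1, e1), (s2, e2) in zip(windows[:-1], windows[1:]):
        if e1 > s2:
            raise ValueError("windows must be non-overlapping and ordered")
    if full_partition is None:
        full_partition, _ = build_partition(g, stations, incidents, config)
    results = []
    for start, end in windows:
        sub = filter_by_period(incidents, start, end)
        part, _ = build_partition(g, stations, sub, config)
        cov = coverage_length(part, g, config.d_max)
        diff = partition_difference_length(part, full_partition, g)
        results.append(WindowResult(
            (pd.Timestamp(start), pd.Timestamp(end)), part, cov, diff,
            part.service_lengths(g), len(sub)))
    return results


# -- segment-table variants (for partition files round-tripped from disk) --


def segment_table_coverage(segments: pd.DataFrame, d_max: float) -> pd.DataFrame:
    """Coverage per station from a partition segment table.

    Uses each segment's recorded far-end expansion-path distance
    (``geom_dist_m``); segments without one (planar mode) count as uncovered.
    Returns columns station_id, length_m, covered_m.
    """
    rows = []
    for sid, grp in segments.groupby("station_id"):
        length = float(grp["length_m"].sum())
        far = pd.to_numeric(grp["geom_dist_m"], errors="coerce")
        near = far - grp["length_m"]
        covered = float(np.clip(d_max - near, 0.0, grp["length_m"])
                        .where(far.notna(), 0.0).sum())
        rows.append({"station_id": sid, "length_m": length,
                     "covered_m": covered})
    return pd.DataFrame(rows)


def segment_table_difference(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Differing-owner length between two partition segment tables that were
    produced on the same (identically lixelized) network."""

    def intervals(df):
        out: dict[int, list[tuple[float, float, int]]] = {}
        for _, r in df.iterrows():
            out.setdefault(int(r["edge_id"]), []).append(
                (float(r["offset_start"]), float(r["offset_end"]),
                 int(r["station_id"])))
        return {k: sorted(v) for k, v in out.items()}

    ia, ib = intervals(a), intervals(b)
    extent_a = {k: (v[0][0], v[-1][1]) for k, v in ia.items()}
    extent_b = {k: (v[0][0], v[-1][1]) for k, v in ib.items()}
    if set(ia) != set(ib) or any(
            abs(extent_a[k][1] - extent_b[k][1]) > 1e-6 for k in ia):
        raise ValueError("partitions do not share the same network edges")
    total = 0.0
    for eid in ia:
        cuts = sorted({c for s, t, _ in ia[eid] + ib[eid] for c in (s, t)})

        def owner(ivs, m):
            for s, t, o in ivs:
                if s <= m < t:
                    return o
            return ivs[-1][2]

        for s, t in zip(cuts[:-1], cuts[1:]):
            if t - s <= GEOM_TOL:
                continue
            m = 0.5 * (s + t)
            if owner(ia[eid], m) != owner(ib[eid], m):
                total += t - s
    return total


def service_length_table(results: list[WindowResult]) -> pd.DataFrame:
    """Per window, the facilities with the longest and shortest service areas
    (the dynamic service-length summary table)."""
    rows = []
    for r in results:
        lens = sorted(r.service_lengths.items(), key=lambda kv: (kv[1], kv[0]))
        shortest_sid, shortest = lens[0]
        longest_sid, longest = max(lens, key=lambda kv: (kv[1], -kv[0]))
        rows.append({
            "window_start": r.window[0], "window_end": r.window[1],
            "n_incidents": r.n_incidents,
            "longest_station": longest_sid, "longest_m": longest,
            "shortest_station": shortest_sid, "shortest_m": shortest,
        })
    return pd.DataFrame(rows)
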