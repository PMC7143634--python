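"""Risk-weighted costs and (constrained) network-Voronoi partitioning.

Edge costs blend normalised geometric length and normalised incident risk,

    W_i = a * L_i / sum(L) + (1 - a) * R_i / sum(R),    a in [0, 1],

so high-risk neighbourhoods are more expensive to claim and the facilities
there keep compact, workload-balanced territories.

Two partitioning modes share a synchronized multi-source expansion in which
all facility operators grow cheapest-cumulative-cost first and every network
node is claimed exactly once (ties go to the lowest station id):

* N-VD — plain network Voronoi: expansion runs to exhaustion; each node goes
  to the operator of minimal cumulative cost.
* C-VD — response-time constrained: in phase 1 an operator may only claim a
  node whose cumulative *geometric* path distance from its own generator is
  within the response radius D_max (e.g. the "Golden 5 min" at 32 km/h,
  about 2667 m); an operator with no claimable frontier pauses. When every
  operator has paused, phase 2 resumes all of them synchronously and the
  remaining nodes are claimed in order of cost accumulated beyond each
  operator's phase-1 frontier (the priority clock resets at resumption).

Expansion priority uses the blended cost W_i while the phase-1 constraint is
tested on metres along the expansion path: competition is risk-weighted but
the response-time limit is a physical distance.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field, replace

from .network import GEOM_TOL, NetGraph, Station

logger = logging.getLogger(__name__)


@dataclass
class CostWeights:
    """Per-edge combined costs W_i (dimensionless; sums to 1 over the graph)."""

    a: float
    weights: dict[int, float]
    risk_fallback_used: bool
    sum_length: float
    sum_risk: float


def edge_costs(g: NetGraph, risks: dict[int, float], a: float) -> CostWeights:
    """Blend normalised length and risk into per-edge costs.

    With zero total risk (no incidents in range of anything) the risk term is
    dropped and costs reduce to normalised lengths, flagged via
    ``risk_fallback_used``.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("weight a must be in [0, 1]")
    if any(risks.get(eid, 0.0) < 0 for eid in g.edges):
        raise ValueError("negative segment risk")
    sum_l = g.total_length
    sum_r = sum(risks.get(eid, 0.0) for eid in g.edges)
    fallback = sum_r <= 0.0
    if fallback:
        logger.warning("total risk is zero; using pure length costs")
        w = {eid: e.length / sum_l for eid, e in g.edges.items()}
    else:
        w = {eid: a * e.length / sum_l + (1.0 - a) * risks.get(eid, 0.0) / sum_r
             for eid, e in g.edges.items()}
    return CostWeights(a, w, fallback, sum_l, sum_r)


@dataclass
class PartitionConfig:
    """Operating point of the partitioner.

    Defaults are the method's standard operating point: equal weight on
    distance and risk (a=0.5), a 1500 m NKDE bandwidth, 100 m lixels, and a
    5-minute response threshold at an average engine speed of 32 km/h.
    """

    a: float = 0.5
    bandwidth: float = 1500.0
    lixel_size: float = 100.0
    speed_kmh: float = 32.0
    time_threshold_min: float = 5.0
    include_projection_distance: bool = False
    mode: str = "cvd"
    phase2_cost_reset: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("a must be in [0, 1]")
        if self.d_max <= 0:
            raise ValueError("derived response radius must be positive")
        if self.mode not in ("cvd", "nvd", "planar"):
            raise ValueError("mode must be cvd, nvd or planar")

    @property
    def d_max(self) -> float:
        """Response radius in metres: speed [km/h] * 1000/60 * time [min]."""
        return self.speed_kmh * 1000.0 / 60.0 * self.time_threshold_min


@dataclass(frozen=True)
class NodeAssignment:
    station_id: int
    cost: float
    geom_dist: float
    phase: int


@dataclass(frozen=True)
class EdgeAssignment:
    """Whole-edge owner, or a split record with a break offset (metres from
    the edge's first endpoint) and an owner on each side."""

    owner: int | None = None
    split_offset: float | None = None
    owner_u: int | None = None
    owner_v: int | None = None

    @property
    def is_split(self) -> bool:
        return self.split_offset is not None


@dataclass
class Partition:
    """Assignment of every reachable network element to a generator."""

    nodes: dict[int, NodeAssignment]
    edges: dict[int, EdgeAssignment]
    unassigned_nodes: set[int]
    stations: dict[int, Station]
    graph_signature: tuple
    meta: dict = field(default_factory=dict)

    def owner_of_node(self, node: int) -> int | None:
        a = self.nodes.get(node)
        return None if a is None else a.station_id

    def edge_intervals(self, g: NetGraph) -> dict[int, list[tuple[float, float, int]]]:
        """Per edge, ordered (start, end, owner) intervals of owned portions."""
        out: dict[int, list[tuple[float, float, int]]] = {}
        for eid, e in g.edges.items():
            ea = self.edges.get(eid)
            if ea is None:
                continue
            if ea.is_split:
                out[eid] = [(0.0, ea.split_offset, ea.owner_u),
                            (ea.split_offset, e.length, ea.owner_v)]
            elif ea.owner is not None:
                out[eid] = [(0.0, e.length, ea.owner)]
        return out

    def service_lengths(self, g: NetGraph) -> dict[int, float]:
        """Total owned network length (metres) per station."""
        out = {sid: 0.0 for sid in self.stations}
        for eid, ivs in self.edge_intervals(g).items():
            for s, t, owner in ivs:
                out[owner] = out.get(owner, 0.0) + (t - s)
        return out


def _seed_entries(stations: list[Station], costs: CostWeights,
                  config: PartitionConfig):
    anchors: dict[int, int] = {}
    for st in stations:
        if st.anchor in anchors:
            raise ValueError(
                f"stations {anchors[st.anchor]} and {st.station_id} share "
                f"anchor node {st.anchor}: ambiguous generators")
        anchors[st.anchor] = st.station_id
    seeds = []
    for st in sorted(stations, key=lambda s: s.station_id):
        if config.include_projection_distance:
            g0 = st.projection_distance
            c0 = config.a * st.projection_distance / costs.sum_length
        else:
            g0, c0 = 0.0, 0.0
        seeds.append((c0, st.station_id, g0, st.anchor))
    return seeds


def _assign_whole_edges(g: NetGraph, nodes: dict[int, NodeAssignment]
                        ) -> dict[int, EdgeAssignment]:
    edges: dict[int, EdgeAssignment] = {}
    for eid, e in g.edges.items():
        ou = nodes.get(e.u)
        ov = nodes.get(e.v)
        if ou is not None and ov is not None and ou.station_id == ov.station_id:
            edges[eid] = EdgeAssignment(owner=ou.station_id)
    return edges


def nvd_partition(g: NetGraph, stations: list[Station],
                  costs: CostWeights,
                  config: PartitionConfig | None = None) -> Partition:
    """Plain network Voronoi: unconstrained synchronized expansion.

    Equivalent to a per-node argmin over single-source cumulative costs,
    with ties to the lowest station id.
    """
    config = config or PartitionConfig(mode="nvd")
    return _expand(g, stations, costs, config, d_max=math.inf)


def cvd_partition(g: NetGraph, stations: list[Station],
                  costs: CostWeights,
                  config: PartitionConfig | None = None,
                  d_max: float | None = None) -> Partition:
    """Constrained network Voronoi with the two-phase response-radius pause."""
    config = config or PartitionConfig(mode="cvd")
    return _expand(g, stations, costs, config,
                   d_max=config.d_max if d_max is None else d_max)


def _expand(g: NetGraph, stations: list[Station], costs: CostWeights,
            config: PartitionConfig, d_max: float) -> Partition:
    if not stations:
        raise ValueError("at least one station is required")
    w = costs.weights
    nodes: dict[int, NodeAssignment] = {}

    # Phase 1: synchronized cheapest-first claims, gated on the operator's own
    # cumulative geometric path distance staying within d_max.
    heap: list[tuple[float, int, float, int]] = []
    for c0, sid, g0, anchor in _seed_entries(stations, costs, config):
        if g0 <= d_max + GEOM_TOL:
            heapq.heappush(heap, (c0, sid, g0, anchor))
    while heap:
        c, sid, gd, node = heapq.heappop(heap)
        if node in nodes:
            continue
        nodes[node] = NodeAssignment(sid, c, gd, 1)
        for eid, other in g.neighbors(node):
            if other in nodes:
                continue
            g2 = gd + g.edges[eid].length
            if g2 <= d_max + GEOM_TOL:
                heapq.heappush(heap, (c + w[eid], sid, g2, other))

    # Phase 2: all operators have reached their response boundary; resume
    # synchronously over the remaining nodes. Priority is the cost accrued
    # beyond each operator's phase-1 frontier (or total cost if the clock is
    # configured to keep running).
    if len(nodes) < len(g.nodes) and math.isfinite(d_max):
        heap2: list[tuple[float, int, float, float, int]] = []
        for node, asg in nodes.items():
            for eid, other in g.neighbors(node):
                if other in nodes:
                    continue
                base = 0.0 if config.phase2_cost_reset else asg.cost
                heapq.heappush(heap2, (base + w[eid], asg.station_id,
                                       asg.geom_dist + g.edges[eid].length,
                                       asg.cost + w[eid], other))
        while heap2:
            key, sid, gd, total, node = heapq.heappop(heap2)
            if node in nodes:
                continue
            nodes[node] = NodeAssignment(sid, total, gd, 2)
            for eid, other in g.neighbors(node):
                if other in nodes:
                    continue
                heapq.heappush(heap2, (key + w[eid], sid,
                                       gd + g.edges[eid].length,
                                       total + w[eid], other))

    unassigned = set(g.nodes) - set(nodes)
    if unassigned:
        logger.info("%d nodes unreachable from any station", len(unassigned))
    return Partition(
        nodes=nodes,
        edges=_assign_whole_edges(g, nodes),
        unassigned_nodes=unassigned,
        stations={st.station_id: st for st in stations},
        graph_signature=g.signature(),
        meta={"mode": config.mode, "a": costs.a, "d_max": d_max,
              "risk_fallback": costs.risk_fallback_used},
    )


def split_boundary_edges(partition: Partition, g: NetGraph,
                         costs: CostWeights) -> Partition:
    """Split every edge whose endpoints belong to different stations at the
    offset where the two cumulative costs meet; each part inherits the nearer
    owner. Exact ties split at the midpoint."""
    w = costs.weights
    for eid, e in g.edges.items():
        if eid in partition.edges:
            continue
        au = partition.nodes.get(e.u)
        av = partition.nodes.get(e.v)
        if au is None or av is None:
            continue  # edge touches an unreachable node; stays unowned
        if au.station_id == av.station_id:
            continue
        wi = w[eid]
        if wi <= 0.0:
            x = e.length / 2.0
        else:
            # cost from u's owner at offset x equals cost from v's owner:
            # au.cost + wi*x/L = av.cost + wi*(L-x)/L
            x = e.length * (av.cost - au.cost + wi) / (2.0 * wi)
        x = min(max(x, GEOM_TOL), e.length - GEOM_TOL)
        partition.edges[eid] = EdgeAssignment(
            split_offset=x, owner_u=au.station_id, owner_v=av.station_id)
    return partition
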