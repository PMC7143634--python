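"""Network kernel density estimation (NKDE) of incident risk.

Historical incident points are projected onto the street network and their
density is evaluated at every graph node of the densified (lixelized) network
with a quartic kernel over shortest-path network distance:

    f(p) = sum_i  (1/h^2) * K(d(p, e_i) / h),   K(u) = 3/4 (1 - u^2) on [0, 1]

where ``h`` is the search bandwidth in metres and ``d`` the network distance
from the sample node to the incident's projection point (including the
incident's partial offset along its host edge — incidents are not snapped to
nodes). Events beyond network distance ``h`` contribute exactly zero.

The normalisation ``1/h^2`` follows the planar-kernel convention even though
densities live on a one-dimensional network; values are therefore in m^-2.
Only ratios of densities matter downstream (they are renormalised in the
cost blend), so the convention is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetGraph, NetworkLocation, dijkstra, project_to_network


def quartic_kernel(u):
    """Quartic (biweight-style) kernel 0.75*(1-u^2) for u in [0,1], else 0.

    ``u`` is the dimensionless ratio distance/bandwidth; scalar or array.
    """
    arr = np.asarray(u, dtype=float)
    if np.any(arr < 0):
        raise ValueError("kernel argument is a distance ratio; must be >= 0")
    out = np.where(arr <= 1.0, 0.75 * (1.0 - arr * arr), 0.0)
    return float(out) if np.isscalar(u) or arr.ndim == 0 else out


@dataclass
class IncidentSet:
    """Incident records with their projections onto a specific graph.

    ``frame`` columns: incident_id, x, y, date (datetime64), edge_id,
    offset, proj_dist.
    """

    frame: pd.DataFrame

    @classmethod
    def from_records(cls, records, g: NetGraph) -> "IncidentSet":
        """Project raw records (incident_id, x, y, date) onto ``g``."""
        rows = []
        for rec in records:
            iid, x, y, date = rec[0], float(rec[1]), float(rec[2]), rec[3]
            loc, d = project_to_network((x, y), g)
            rows.append((iid, x, y, pd.Timestamp(date), loc.edge_id,
                         loc.offset, d))
        frame = pd.DataFrame(
            rows, columns=["incident_id", "x", "y", "date", "edge_id",
                           "offset", "proj_dist"])
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def locations(self) -> list[NetworkLocation]:
        return [NetworkLocation(int(e), float(o))
                for e, o in zip(self.frame["edge_id"], self.frame["offset"])]


def filter_by_period(incidents: IncidentSet, start, end) -> IncidentSet:
    """Records with start <= date < end (half-open, so consecutive monthly
    windows partition a period without double counting)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start > end:
        raise ValueError("start must be <= end")
    m = (incidents.frame["date"] >= start) & (incidents.frame["date"] < end)
    return IncidentSet(incidents.frame[m].reset_index(drop=True))


@dataclass
class RiskField:
    """NKDE values at graph nodes for one bandwidth."""

    bandwidth: float
    values: dict[int, float]
    kernel: str = "quartic"

    def value(self, node: int) -> float:
        return self.values.get(node, 0.0)


def nkde(g: NetGraph, incidents: IncidentSet, h: float) -> RiskField:
    """Evaluate the incident kernel density at every node of ``g``.

    Incidents are grouped by host edge; one bounded Dijkstra per host-edge
    endpoint (cutoff ``h``) yields exact network distances
    ``d = min(d(node,u) + offset, d(node,v) + length - offset)``.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if not g.densified:
        raise ValueError("nkde requires a densified graph")
    values = {n: 0.0 for n in g.nodes}
    if len(incidents) == 0:
        return RiskField(h, values)
    inv_h2 = 1.0 / (h * h)
    by_edge: dict[int, list[float]] = {}
    for loc in incidents.locations():
        if loc.edge_id not in g.edges:
            raise KeyError(f"incident host edge {loc.edge_id} not in graph")
        by_edge.setdefault(loc.edge_id, []).append(loc.offset)
    for eid in sorted(by_edge):
        e = g.edges[eid]
        du = dijkstra(g, [(e.u, 0.0)], "length", cutoff=h)
        dv = dijkstra(g, [(e.v, 0.0)], "length", cutoff=h)
        for off in by_edge[eid]:
            for node in set(du) | set(dv):
                d = min(du.get(node, np.inf) + off,
                        dv.get(node, np.inf) + e.length - off)
                if d <= h:
                    values[node] += inv_h2 * quartic_kernel(d / h)
    return RiskField(h, values)


def segment_risk(field: RiskField, g: NetGraph) -> dict[int, float]:
    """Per-edge risk R_i as the mean of the field at the edge's endpoints.

    The endpoint mean keeps R_i independent of the lixel resolution (a
    length-weighted integral would not add information at lixel scale).
    """
    return {eid: 0.5 * (field.value(e.u) + field.value(e.v))
            for eid, e in g.edges.items()}
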