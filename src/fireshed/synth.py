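"""Seeded synthetic street networks, stations and clustered incidents.

The generator emulates, at reduced scale, the statistical structure of a
dense urban fire dataset: a connected, jittered grid street network with
random edge dropout; a handful of well-separated facility points sitting a
few tens of metres off the network; and incident points clustered around a
few hotspots, with monthly Poisson counts and dates.

All randomness flows from one seed through a named stream per component
(network / stations / incidents), so changing one component's parameters
does not perturb the draws of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString

_STREAMS = {"network": 0, "stations": 1, "incidents": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31),
                                                         _STREAMS[stream]]))


@dataclass(frozen=True)
class Hotspot:
    """Incident cluster: centre (metres), Gaussian spatial spread (metres),
    expected events per month."""

    x: float
    y: float
    spread: float
    rate: float


@dataclass
class SynthConfig:
    rows: int = 10
    cols: int = 10
    spacing: float = 250.0
    jitter: float = 0.1          # fraction of spacing
    dropout: float = 0.08        # per-edge removal probability
    n_stations: int = 3
    min_sep: float = 800.0       # metres between station raw points
    hotspots: tuple[Hotspot, ...] = ()
    months: int = 3
    start: str = "2015-03-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not 0.0 <= self.jitter < 0.5:
            raise ValueError("jitter must be in [0, 0.5)")
        if not 0.0 <= self.dropout < 0.3:
            raise ValueError("dropout must be in [0, 0.3)")


def _connected(n_nodes: int, edges: list[tuple[int, int]]) -> bool:
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    return len({find(i) for i in range(n_nodes)}) == 1


def gen_network(config: SynthConfig) -> list[LineString]:
    """Jittered rows x cols grid with random edge dropout; connectivity is
    enforced by re-drawing the dropout (up to 100 attempts)."""
    rng = _rng(config.seed, "network")
    r, c, s = config.rows, config.cols, config.spacing
    jit = rng.uniform(-config.jitter * s, config.jitter * s, size=(r * c, 2))
    pos = np.array([(j * s, i * s) for i in range(r) for j in range(c)]) + jit
    all_edges = []
    for i in range(r):
        for j in range(c):
            n = i * c + j
            if j + 1 < c:
                all_edges.append((n, n + 1))
            if i + 1 < r:
                all_edges.append((n, n + c))
    for _ in range(100):
        keep = [e for e in all_edges if rng.random() >= config.dropout]
        if _connected(r * c, keep):
            return [LineString([pos[u], pos[v]]) for u, v in keep]
    raise RuntimeError("could not generate a connected network in 100 attempts")


def _line_endpoints(features: list[LineString]) -> np.ndarray:
    pts = set()
    for f in features:
        coords = list(f.coords)
        pts.add(tuple(coords[0]))
        pts.add(tuple(coords[-1]))
    return np.array(sorted(pts))


def gen_stations(features: list[LineString], n: int, min_sep: float,
                 seed: int) -> list[tuple[int, float, float]]:
    """Place ``n`` facility points near randomly chosen network nodes, offset
    up to 50 m off-network (so projection is exercised), pairwise at least
    ``min_sep`` apart."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed, "stations")
    nodes = _line_endpoints(features)
    chosen: list[np.ndarray] = []
    for _ in range(1000):
        cand = nodes[rng.integers(len(nodes))]
        if all(math.hypot(*(cand - p)) >= min_sep for p in chosen):
            chosen.append(cand)
            if len(chosen) == n:
                break
    else:
        raise RuntimeError(f"could not place {n} stations >= {min_sep} m "
                           "apart in 1000 draws")
    out = []
    for sid, base in enumerate(chosen, start=1):
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, 50.0)
        out.append((sid, float(base[0] + rad * math.cos(ang)),
                    float(base[1] + rad * math.sin(ang))))
    return out


def gen_incidents(features: list[LineString], hotspots, months: int,
                  seed: int, start: str = "2015-03-01") -> pd.DataFrame:
    """Clustered incident points on the network with monthly time stamps.

    Per month and hotspot, a Poisson count of events is placed on edges
    chosen with probability proportional to a Gaussian decay of the edge
    midpoint's distance to the hotspot centre, at a uniform offset along the
    edge. Dates are uniform within the month. Every incident lies exactly on
    the network by construction.
    """
    if not hotspots:
        raise ValueError("at least one hotspot is required")
    rng = _rng(seed, "incidents")
    mids = np.array([f.interpolate(0.5, normalized=True).coords[0]
                     for f in features])
    lengths = np.array([f.length for f in features])
    month_edges = pd.date_range(pd.Timestamp(start).normalize().replace(day=1),
                                periods=months + 1, freq="MS")
    rows = []
    iid = 0
    for m in range(months):
        t0, t1 = month_edges[m], month_edges[m + 1]
        span = (t1 - t0).total_seconds()
        for hs in hotspots:
            count = int(rng.poisson(hs.rate))
            if count == 0:
                continue
            d2 = (mids[:, 0] - hs.x) ** 2 + (mids[:, 1] - hs.y) ** 2
            d2 = d2 - d2.min()  # shift so the nearest edge survives underflow
            if hs.spread > 0:
                p = np.exp(-d2 / (2.0 * hs.spread ** 2))
            else:
                p = (d2 <= 1e-9).astype(float)
            p = p / p.sum()
            for k in rng.choice(len(features), size=count, p=p):
                off = rng.uniform(0.0, lengths[k])
                pt = features[k].interpolate(off)
                date = t0 + pd.Timedelta(seconds=float(rng.uniform(0, span)))
                rows.append((iid, float(pt.x), float(pt.y), date))
                iid += 1
    return pd.DataFrame(rows, columns=["incident_id", "x", "y", "date"])


def generate(config: SynthConfig):
    """Network features, stations and incidents for one configuration."""
    features = gen_network(config)
    stations = gen_stations(features, config.n_stations, config.min_sep,
                            config.seed)
    incidents = gen_incidents(features, config.hotspots, config.months,
                              config.seed, config.start)
    return features, stations, incidents


# -- versioned fixtures -----------------------------------------------------


def fixture_basic():
    """Two stations at the ends of a straight symmetric 1000 m street, no
    incidents: with a = 1 the partition must split at the midpoint."""
    features = [LineString([(0, 0), (500, 0)]),
                LineString([(500, 0), (1000, 0)])]
    stations = [(1, 0.0, 5.0), (2, 1000.0, 5.0)]
    incidents = pd.DataFrame(columns=["incident_id", "x", "y", "date"])
    return features, stations, incidents


def fixture_hotspot(rate: float = 10.0, months: int = 6, seed: int = 7):
    """An 8 km street with stations at both ends and an incident hotspot
    near station 1 (x=800): with a < 1 station 1's territory shrinks, and
    the street is long enough for a 5-min response radius to bind."""
    features = [LineString([(x, 0), (x + 200, 0)]) for x in range(0, 8000, 200)]
    stations = [(1, 0.0, 10.0), (2, 8000.0, 10.0)]
    incidents = gen_incidents(features, [Hotspot(800.0, 0.0, 300.0, rate)],
                              months, seed)
    return features, stations, incidents


def fixture_uroad():
    """Planar-enclave trap: a dead-end detour road whose far end is
    Euclidean-near station 2 but network-reachable only through station 1's
    side, so the planar Thiessen baseline fragments station 2's area."""
    main = [LineString([(x, 0), (x + 200, 0)]) for x in range(0, 2000, 200)]
    detour = [LineString([(0, 0), (0, 300)])]
    detour += [LineString([(x, 300), (x + 190, 300)]) for x in range(0, 1900, 190)]
    features = main + detour
    stations = [(1, 0.0, -10.0), (2, 2000.0, -10.0)]
    incidents = pd.DataFrame(columns=["incident_id", "x", "y", "date"])
    return features, stations, incidents


def city_config(seed: int = 0, rows: int = 20, cols: int = 20,
                n_stations: int = 5, n_hotspots: int = 3,
                months: int = 12, rate: float = 8.0,
                background_rate: float = 8.0) -> SynthConfig:
    """The synthetic-city configuration: a rows x cols jittered grid at 250 m
    spacing with well-separated stations and clustered monthly incidents.

    Hotspot centres are drawn from the incidents stream inside the grid
    extent with a 400 m spread. Urban incident patterns combine local
    clusters with a diffuse city-wide component, so a broad background
    hotspot (spread 0.6x the grid extent) contributes ``background_rate``
    further events per month; without it, density support would vanish
    almost everywhere at small bandwidths, which real incident data does
    not do.
    """
    rng = _rng(seed, "incidents")
    w, h = (cols - 1) * 250.0, (rows - 1) * 250.0
    hotspots = tuple(
        Hotspot(float(rng.uniform(0.15 * w, 0.85 * w)),
                float(rng.uniform(0.15 * h, 0.85 * h)), 400.0, rate)
        for _ in range(n_hotspots))
    if background_rate > 0:
        hotspots += (Hotspot(w / 2.0, h / 2.0, 0.6 * max(w, h),
                             background_rate),)
    return SynthConfig(rows=rows, cols=cols, spacing=250.0, jitter=0.1,
                       dropout=0.08, n_stations=n_stations,
                       min_sep=min(w, h) / 3.0, hotspots=hotspots,
                       months=months, seed=seed)


def fixture_city(seed: int = 0, **kwargs):
    """Generated city instance (defaults: 20x20 grid, 5 stations, 3 hotspots,
    12 months). Keyword overrides pass through to :func:`city_config`."""
    return generate(city_config(seed=seed, **kwargs))
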