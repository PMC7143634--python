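"""Shared fixtures: seeded random mini-networks and a cached suite of
synthetic-city pipeline runs reused by several slow tests."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import LineString

import fireshed as fs


def random_line_features(rng: np.random.Generator, n_nodes: int,
                         extra_edges: int = 3) -> list[LineString]:
    """Connected random planar-ish network: a random spanning tree over
    scattered points plus a few extra chords. Edge lengths are the Euclidean
    point distances, so geometry and topology stay consistent."""
    pts = rng.uniform(0, 2000, size=(n_nodes, 2))
    feats = []
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        feats.append(LineString([pts[j], pts[i]]))
    for _ in range(extra_edges):
        i, j = rng.integers(0, n_nodes, size=2)
        if i != j:
            feats.append(LineString([pts[i], pts[j]]))
    return feats


def random_netgraph(rng: np.random.Generator, n_nodes: int,
                    extra_edges: int = 3) -> fs.NetGraph:
    return fs.build_topology(random_line_features(rng, n_nodes, extra_edges),
                             snap_tolerance=0.5)


def netgraph_to_networkx(g: fs.NetGraph, weight_map=None):
    """Independent-view conversion for oracle checks (min over parallels)."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(g.nodes)
    for eid, e in g.edges.items():
        w = e.length if weight_map is None else weight_map[eid]
        if G.has_edge(e.u, e.v):
            G[e.u][e.v]["weight"] = min(G[e.u][e.v]["weight"], w)
        else:
            G.add_edge(e.u, e.v, weight=w)
    return G


def naive_nkde(g: fs.NetGraph, iset, h: float) -> dict[int, float]:
    """Independent NKDE oracle: insert each incident as a real graph node in
    a fresh copy and run a plain shortest-path sweep from it; sum kernels
    over all (node, incident) pairs."""
    import math

    from fireshed.network import dijkstra

    expect = {n: 0.0 for n in g.nodes}
    for _, rec in iset.frame.iterrows():
        gc = g.copy()
        e = gc.edges[int(rec["edge_id"])]
        off = float(rec["offset"])
        if off <= 1e-6:
            src = e.u
        elif off >= e.length - 1e-6:
            src = e.v
        else:
            src, _, _ = gc.split_edge(int(rec["edge_id"]), off)
        dist = dijkstra(gc, [(src, 0.0)], "length", cutoff=math.inf)
        for n in g.nodes:
            d = dist.get(n, math.inf)
            if d <= h:
                expect[n] += (1 / h**2) * fs.quartic_kernel(d / h)
    return expect


CITY_KW = dict(rows=10, cols=10, n_stations=3, n_hotspots=2, months=3)


def city_instance(seed: int, mode_thresholds=(5.0, 10.0, 15.0)):
    """One reduced synthetic-city run: N-VD plus C-VD at several response
    thresholds, with coverage and enclave counts for each."""
    feats, st_pts, inc = fs.fixture_city(seed=seed, **CITY_KW)
    cfg = fs.PartitionConfig(mode="nvd")
    g, stations = fs.prepare_graph(feats, st_pts, cfg)
    iset = fs.project_incidents(inc, g)
    out = {"graph": g, "stations": stations, "incidents": iset}
    nvd, costs = fs.build_partition(g, stations, iset, cfg)
    out["costs"] = costs
    out["nvd"] = nvd
    out["nvd_cov"] = {t: fs.coverage_length(nvd, g, fs.PartitionConfig(
        time_threshold_min=t).d_max) for t in mode_thresholds}
    out["cvd"] = {}
    out["cvd_cov"] = {}
    for t in mode_thresholds:
        ccfg = fs.PartitionConfig(mode="cvd", time_threshold_min=t)
        part, _ = fs.build_partition(g, stations, iset, ccfg)
        out["cvd"][t] = part
        out["cvd_cov"][t] = fs.coverage_length(part, g, ccfg.d_max)
    return out


@pytest.fixture(scope="session")
def city_suite():
    """50 seeded reduced city instances (shared across slow tests)."""
    return [city_instance(seed) for seed in range(50)]


@pytest.fixture(scope="session")
def city_one():
    """A single standard reduced city instance (seed 0)."""
    return city_instance(0)
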