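"""Planar baseline, coverage, difference, enclaves and dynamic runs."""

import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

import fireshed as fs


def _line_pipeline(length, station_xs, lixel=100.0, a=1.0, mode="nvd"):
    g = fs.build_topology([LineString([(0, 0), (length, 0)])])
    stations = []
    for sid, x in enumerate(station_xs, start=1):
        _, st = fs.insert_station(g, sid, (x, 5.0))
        stations.append(st)
    fs.densify(g, lixel)
    cw = fs.edge_costs(g, {eid: 0.0 for eid in g.edges}, a=a)
    if mode == "planar":
        part = fs.planar_thiessen_partition(stations, g)
    else:
        fn = fs.cvd_partition if mode == "cvd" else fs.nvd_partition
        part = fs.split_boundary_edges(fn(g, stations, cw), g, cw)
    return g, stations, part, cw


class TestPlanarThiessen:
    def test_symmetric_line_midpoint(self):
        g, _, part, _ = _line_pipeline(1000.0, [0.0, 1000.0], mode="planar")
        lens = part.service_lengths(g)
        assert lens[1] == pytest.approx(500.0, abs=50.0)  # lixel resolution
        assert lens[1] + lens[2] == pytest.approx(1000.0)

    def test_agrees_with_exhaustive_nearest_at_midpoints(self):
        feats, st_pts, inc = fs.fixture_city(seed=4, rows=6, cols=6,
                                             n_stations=3, n_hotspots=1,
                                             months=1)
        cfg = fs.PartitionConfig(mode="planar")
        g, stations = fs.prepare_graph(feats, st_pts, cfg)
        part = fs.planar_thiessen_partition(stations, g)
        raw = {st.station_id: st.raw for st in stations}
        for eid, e in g.edges.items():
            m = e.geom.interpolate(0.5, normalized=True)
            best = min((math.hypot(raw[s][0] - m.x, raw[s][1] - m.y), s)
                       for s in raw)
            assert part.edges[eid].owner == best[1]

    def test_single_station_owns_everything(self):
        g, _, part, _ = _line_pipeline(1000.0, [300.0], mode="planar")
        assert part.service_lengths(g)[1] == pytest.approx(g.total_length)

    def test_coincident_stations_rejected(self):
        g = fs.build_topology([LineString([(0, 0), (1000, 0)])])
        _, s1 = fs.insert_station(g, 1, (100.0, 5.0))
        s2 = fs.Station(2, s1.raw, None, 0.0, s1.anchor)
        with pytest.raises(ValueError, match="coincident"):
            fs.planar_thiessen_partition([s1, s2], g)


class TestCoverageLength:
    D = fs.PartitionConfig().d_max  # 2666.67 m

    def test_truncation_from_line_end(self):
        g, _, part, _ = _line_pipeline(5000.0, [0.0])
        cov = fs.coverage_length(part, g, self.D)
        assert cov.per_station_covered[1] == pytest.approx(self.D, abs=1e-3)

    def test_central_station_covers_both_arms(self):
        g, _, part, _ = _line_pipeline(4000.0, [2000.0])
        cov = fs.coverage_length(part, g, self.D)
        assert cov.per_station_covered[1] == pytest.approx(4000.0, abs=1e-3)

    def test_covered_at_most_assigned(self, city_suite):
        for inst in city_suite[:10]:
            for cov in (inst["nvd_cov"][5.0], inst["cvd_cov"][5.0]):
                for sid, c in cov.per_station_covered.items():
                    assert c <= cov.per_station_total[sid] + 1e-6

    def test_empty_service_area_covers_zero(self):
        g, stations, part, _ = _line_pipeline(1000.0, [0.0, 1000.0])
        # station 2 stripped of all territory
        part.edges = {eid: ea for eid, ea in part.edges.items()
                      if ea.owner == 1}
        cov = fs.coverage_length(part, g, self.D)
        assert cov.per_station_covered[2] == 0.0


class TestDifferenceLength:
    def test_identity_is_zero(self, city_one):
        d = fs.partition_difference_length(city_one["nvd"], city_one["nvd"],
                                           city_one["graph"])
        assert d.total_m == 0.0

    def test_swapped_owners_give_total_length(self):
        g, _, p1, cw = _line_pipeline(1000.0, [0.0, 1000.0])
        g2 = fs.build_topology([LineString([(0, 0), (1000, 0)])])
        stations2 = []
        for sid, x in ((2, 0.0), (1, 1000.0)):  # ids swapped
            _, st = fs.insert_station(g2, sid, (x, 5.0))
            stations2.append(st)
        fs.densify(g2, 100.0)
        cw2 = fs.edge_costs(g2, {eid: 0.0 for eid in g2.edges}, a=1.0)
        p2 = fs.split_boundary_edges(
            fs.nvd_partition(g2, stations2, cw2), g2, cw2)
        d = fs.partition_difference_length(p1, p2, g)
        assert d.total_m == pytest.approx(g.total_length, abs=1e-3)

    def test_single_lixel_reassignment_is_local(self, city_one):
        import copy

        from fireshed.partition import EdgeAssignment

        g = city_one["graph"]
        p1 = city_one["nvd"]
        p2 = copy.deepcopy(p1)
        eid = next(e for e, ea in p2.edges.items()
                   if not ea.is_split and ea.owner is not None)
        other = next(s for s in p2.stations if s != p2.edges[eid].owner)
        p2.edges[eid] = EdgeAssignment(owner=other)
        d = fs.partition_difference_length(p1, p2, g)
        assert d.total_m == pytest.approx(g.edges[eid].length)

    def test_symmetry_and_triangle(self, city_one):
        g = city_one["graph"]
        p5, p10, p15 = (city_one["cvd"][t] for t in (5.0, 10.0, 15.0))
        d_ab = fs.partition_difference_length(p5, p10, g).total_m
        d_ba = fs.partition_difference_length(p10, p5, g).total_m
        d_ac = fs.partition_difference_length(p5, p15, g).total_m
        d_bc = fs.partition_difference_length(p10, p15, g).total_m
        assert d_ab == pytest.approx(d_ba, abs=1e-9)
        assert d_ac <= d_ab + d_bc + 1e-6

    def test_different_graphs_rejected(self, city_one):
        g2, _, p2, _ = _line_pipeline(1000.0, [0.0, 1000.0])
        with pytest.raises(ValueError):
            fs.partition_difference_length(city_one["nvd"], p2,
                                           city_one["graph"])

    def test_region_breakdown_sums_to_total(self, city_one):
        g = city_one["graph"]
        xs = [x for x, _ in g.nodes.values()]
        ys = [y for _, y in g.nodes.values()]
        mid = (min(xs) + max(xs)) / 2
        pad = 1000.0
        west = Polygon([(min(xs) - pad, min(ys) - pad), (mid, min(ys) - pad),
                        (mid, max(ys) + pad), (min(xs) - pad, max(ys) + pad)])
        east = Polygon([(mid, min(ys) - pad), (max(xs) + pad, min(ys) - pad),
                        (max(xs) + pad, max(ys) + pad), (mid, max(ys) + pad)])
        d = fs.partition_difference_length(
            city_one["nvd"], city_one["cvd"][5.0], g,
            regions=[("west", west), ("east", east)])
        assert sum(d.by_region.values()) == pytest.approx(d.total_m)
        assert d.by_region["<outside>"] == pytest.approx(0.0)


class TestEnclaveCheck:
    def test_network_partitions_are_contiguous(self, city_one):
        g = city_one["graph"]
        for part in (city_one["nvd"], city_one["cvd"][5.0]):
            assert set(fs.enclave_check(part, g).values()) <= {0, 1}

    def test_planar_uroad_has_enclave(self):
        feats, st_pts, inc = fs.fixture_uroad()
        res = fs.run(feats, st_pts, inc, fs.PartitionConfig(mode="planar"))
        assert max(res.enclaves.values()) >= 2

    def test_single_station_single_component(self):
        g, _, part, _ = _line_pipeline(1000.0, [300.0])
        assert fs.enclave_check(part, g) == {1: 1}


class TestDynamicRun:
    def _setup(self, incidents, months=3):
        feats, st_pts, _ = fs.fixture_city(seed=8, rows=8, cols=8,
                                           n_stations=3, n_hotspots=1,
                                           months=months)
        cfg = fs.PartitionConfig(mode="cvd")
        g, stations = fs.prepare_graph(feats, st_pts, cfg)
        iset = fs.project_incidents(incidents, g)
        return g, stations, iset, cfg

    def test_identical_window_patterns_give_identical_partitions(self):
        feats, st_pts, _ = fs.fixture_city(seed=8, rows=8, cols=8,
                                           n_stations=3, n_hotspots=1,
                                           months=1)
        base = fs.fixture_city(seed=8, rows=8, cols=8, n_stations=3,
                               n_hotspots=1, months=1)[2]
        # replicate the same spatial pattern into three months
        frames = []
        for k, month in enumerate(["2015-03", "2015-04", "2015-05"]):
            f = base.copy()
            f["date"] = pd.Timestamp(f"{month}-15")
            f["incident_id"] = f["incident_id"] + k * len(f)
            frames.append(f)
        inc = pd.concat(frames, ignore_index=True)
        cfg = fs.PartitionConfig(mode="cvd")
        g, stations = fs.prepare_graph(feats, st_pts, cfg)
        iset = fs.project_incidents(inc, g)
        res = fs.dynamic_run(g, stations, iset,
                             fs.monthly_windows("2015-03-01", 3), cfg)
        sl0 = res[0].service_lengths
        for r in res[1:]:
            assert r.service_lengths == sl0
            assert fs.partition_difference_length(
                r.partition, res[0].partition, g).total_m == 0.0

    def test_window_service_lengths_conserve_assigned_length(self):
        feats, st_pts, inc = fs.fixture_city(seed=9, rows=8, cols=8,
                                             n_stations=3, n_hotspots=2,
                                             months=3)
        cfg = fs.PartitionConfig(mode="cvd")
        g, stations = fs.prepare_graph(feats, st_pts, cfg)
        iset = fs.project_incidents(inc, g)
        res = fs.dynamic_run(g, stations, iset,
                             fs.monthly_windows("2015-03-01", 3), cfg)
        for r in res:
            assigned = sum(t - s for ivs in
                           r.partition.edge_intervals(g).values()
                           for s, t, _ in ivs)
            assert sum(r.service_lengths.values()) == pytest.approx(assigned)

    def test_moving_hotspot_shifts_service_length(self):
        """Hotspot sits near station 1 in the first half-year and near
        station 2 in the second: with a < 1, station 1's area is smaller
        while the risk burden is on its side."""
        feats = [LineString([(x, 0), (x + 200, 0)])
                 for x in range(0, 4000, 200)]
        st_pts = [(1, 0.0, 10.0), (2, 4000.0, 10.0)]
        near1 = fs.gen_incidents(feats, [fs.Hotspot(400.0, 0.0, 150.0, 25.0)],
                                 6, seed=21, start="2015-01-01")
        near2 = fs.gen_incidents(feats, [fs.Hotspot(3600.0, 0.0, 150.0, 25.0)],
                                 6, seed=22, start="2015-07-01")
        near2["incident_id"] += len(near1)
        inc = pd.concat([near1, near2], ignore_index=True)
        cfg = fs.PartitionConfig(mode="nvd", a=0.3)
        g, stations = fs.prepare_graph(feats, st_pts, cfg)
        iset = fs.project_incidents(inc, g)
        windows = [(pd.Timestamp("2015-01-01"), pd.Timestamp("2015-07-01")),
                   (pd.Timestamp("2015-07-01"), pd.Timestamp("2016-01-01"))]
        res = fs.dynamic_run(g, stations, iset, windows, cfg)
        assert res[0].service_lengths[1] <= res[1].service_lengths[1]

    def test_empty_window_uses_fallback(self):
        feats, st_pts, inc = fs.fixture_city(seed=10, rows=6, cols=6,
                                             n_stations=2, n_hotspots=1,
                                             months=1)
        cfg = fs.PartitionConfig(mode="cvd")
        g, stations = fs.prepare_graph(feats, st_pts, cfg)
        iset = fs.project_incidents(inc, g)
        windows = [(pd.Timestamp("2020-01-01"), pd.Timestamp("2020-02-01"))]
        res = fs.dynamic_run(g, stations, iset, windows, cfg)
        assert res[0].n_incidents == 0
        assert len(res[0].partition.nodes) > 0

    def test_service_length_table_shape(self):
        feats, st_pts, inc = fs.fixture_city(seed=9, rows=8, cols=8,
                                             n_stations=3, n_hotspots=2,
                                             months=3)
        cfg = fs.PartitionConfig(mode="cvd")
        g, stations = fs.prepare_graph(feats, st_pts, cfg)
        iset = fs.project_incidents(inc, g)
        res = fs.dynamic_run(g, stations, iset,
                             fs.monthly_windows("2015-03-01", 3), cfg)
        tab = fs.service_length_table(res)
        assert len(tab) == 3
        assert (tab["longest_m"] >= tab["shortest_m"]).all()
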