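"""Readers and writers for the package's on-disk formats.

Geometry travels as GeoJSON FeatureCollections (plain ``json`` plus shapely
``shape``/``mapping``); tables as headed CSV. Coordinates are assumed to be
in a projected metric CRS already — no reprojection happens here.

CSV dialects:
  network    ``edge_id,wkt``  or  ``edge_id,x1,y1,x2,y2,...``
  stations   ``station_id,x,y``
  incidents  ``incident_id,x,y,date``   (ISO-8601 dates)
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape
from shapely import wkt as _wkt
from shapely.ops import substring

from .network import NetGraph
from .partition import Partition
from .risk import RiskField


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _dump(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


# -- network ----------------------------------------------------------------


def read_network(path) -> list[LineString]:
    """Street polylines from GeoJSON or CSV (see module docstring)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        feats = []
        if "wkt" in df.columns:
            for _, row in df.iterrows():
                feats.append(_wkt.loads(row["wkt"]))
        else:
            coord_cols = [c for c in df.columns if c != "edge_id"]
            for _, row in df.iterrows():
                vals = [row[c] for c in coord_cols
                        if not (isinstance(row[c], float) and math.isnan(row[c]))]
                feats.append(LineString(list(zip(vals[0::2], vals[1::2]))))
        return feats
    data = json.loads(path.read_text())
    feats = []
    for f in data["features"]:
        geom = shape(f["geometry"])
        if geom.geom_type == "LineString":
            feats.append(geom)
        elif geom.geom_type == "MultiLineString":
            feats.extend(geom.geoms)
        else:
            raise ValueError(f"unsupported network geometry {geom.geom_type}")
    return feats


def write_network_geojson(g: NetGraph, path) -> None:
    feats = []
    for eid in sorted(g.edges):
        e = g.edges[eid]
        feats.append({
            "type": "Feature",
            "geometry": mapping(e.geom),
            "properties": {"edge_id": eid, "parent_edge_id": e.parent,
                           "length_m": round(e.length, 6)},
        })
    _dump(_feature_collection(feats), path)


def write_features_geojson(features: list[LineString], path) -> None:
    feats = [{"type": "Feature", "geometry": mapping(f),
              "properties": {"edge_id": i}} for i, f in enumerate(features)]
    _dump(_feature_collection(feats), path)


# -- points -----------------------------------------------------------------


def read_stations(path) -> list[tuple[int, float, float]]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        return [(int(r["station_id"]), float(r["x"]), float(r["y"]))
                for _, r in df.iterrows()]
    data = json.loads(path.read_text())
    out = []
    for i, f in enumerate(data["features"]):
        geom = shape(f["geometry"])
        props = f.get("properties") or {}
        out.append((int(props.get("station_id", i + 1)), geom.x, geom.y))
    return out


def write_stations_geojson(stations, path) -> None:
    feats = [{"type": "Feature", "geometry": mapping(Point(x, y)),
              "properties": {"station_id": sid}} for sid, x, y in stations]
    _dump(_feature_collection(feats), path)


def read_incidents(path) -> list[tuple]:
    """Incident records (incident_id, x, y, date)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, parse_dates=["date"])
        return [(r["incident_id"], float(r["x"]), float(r["y"]), r["date"])
                for _, r in df.iterrows()]
    data = json.loads(path.read_text())
    out = []
    for i, f in enumerate(data["features"]):
        geom = shape(f["geometry"])
        props = f.get("properties") or {}
        out.append((props.get("incident_id", i), geom.x, geom.y,
                    pd.Timestamp(props["date"])))
    return out


def write_incidents_geojson(incidents: pd.DataFrame, path) -> None:
    feats = []
    for _, r in incidents.iterrows():
        feats.append({
            "type": "Feature",
            "geometry": mapping(Point(r["x"], r["y"])),
            "properties": {"incident_id": int(r["incident_id"]),
                           "date": pd.Timestamp(r["date"]).isoformat()},
        })
    _dump(_feature_collection(feats), path)


# -- density ----------------------------------------------------------------


def write_density_geojson(field: RiskField, g: NetGraph, path) -> None:
    feats = []
    for nid in sorted(g.nodes):
        x, y = g.nodes[nid]
        feats.append({
            "type": "Feature",
            "geometry": mapping(Point(x, y)),
            "properties": {"node_id": nid, "density": field.value(nid)},
        })
    _dump(_feature_collection(feats), path)


def write_density_csv(field: RiskField, g: NetGraph, path) -> None:
    pd.DataFrame({"node_id": sorted(g.nodes),
                  "density": [field.value(n) for n in sorted(g.nodes)]}
                 ).to_csv(path, index=False)


# -- partitions -------------------------------------------------------------


def write_partition_geojson(partition: Partition, g: NetGraph, path,
                            d_max: float | None = None) -> None:
    """Owned (possibly split) segments with ownership and reach properties.

    ``geom_dist_m`` is the geometric distance from the owning facility to the
    segment's far end along the expansion path (null for the planar mode,
    which has no network sweep); ``within_threshold`` marks segments entirely
    inside the response radius.
    """
    feats = []
    for eid in sorted(g.edges):
        ea = partition.edges.get(eid)
        if ea is None:
            continue
        e = g.edges[eid]
        pieces: list[tuple[float, float, int]] = []
        if ea.is_split:
            pieces = [(0.0, ea.split_offset, ea.owner_u),
                      (ea.split_offset, e.length, ea.owner_v)]
        else:
            pieces = [(0.0, e.length, ea.owner)]
        for start, end, sid in pieces:
            geom = e.geom if (start == 0.0 and end == e.length) else \
                substring(e.geom, start, end)
            far = cost = phase = None
            if ea.is_split:
                # the owning endpoint is the near end; the break is the far end
                node = e.u if start == 0.0 else e.v
                asg = partition.nodes.get(node)
                if asg is not None and asg.station_id == sid:
                    far = asg.geom_dist + (end - start)
                    cost, phase = asg.cost, asg.phase
            else:
                au = partition.nodes.get(e.u)
                av = partition.nodes.get(e.v)
                if au is not None and av is not None and \
                        au.station_id == sid and av.station_id == sid:
                    deep = max(au, av, key=lambda a: a.geom_dist)
                    far, cost = deep.geom_dist, deep.cost
                    phase = max(au.phase, av.phase)
            if partition.meta.get("mode") == "planar":
                far = cost = phase = None
            props = {
                "edge_id": eid, "parent_edge_id": e.parent,
                "offset_start": round(start, 6), "offset_end": round(end, 6),
                "length_m": round(end - start, 6),
                "station_id": sid, "cost": cost, "geom_dist_m": far,
                "phase": phase,
                "within_threshold": (None if (far is None or d_max is None)
                                     else bool(far <= d_max + 1e-6)),
            }
            feats.append({"type": "Feature", "geometry": mapping(geom),
                          "properties": props})
    _dump(_feature_collection(feats), path)


def read_partition_segments(path) -> pd.DataFrame:
    """Partition GeoJSON back as a segment table (for CLI-level metrics)."""
    data = json.loads(Path(path).read_text())
    rows = [f["properties"] for f in data["features"]]
    return pd.DataFrame(rows)
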