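"""Readers and writers for the package's plain-text formats.

Vector layers travel as GeoJSON FeatureCollections (networks as Point +
LineString features, facilities as Points, flood masks as Polygon /
MultiPolygon), rasters as Esri ASCII grids, tables as CSV.  All coordinates
are projected meters; the CRS is a recorded string in a JSON sidecar and
mixing CRSs across inputs is a hard error — the tools never reproject.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .floodmask import FloodMask
from .grids import FrictionGrid, GridFrame, PopulationGrid, Raster, TimeGrid
from .network import Edge, Facility, FacilitySet, RoadNetwork

DEFAULT_CRS = "local-projected-meters"

_NODATA = -9999.0


def _fc(features: list[dict], crs: str) -> dict:
    return {"type": "FeatureCollection", "crs_name": crs, "features": features}


# --- road networks ---------------------------------------------------------


def write_network_geojson(
    network: RoadNetwork,
    path: str | Path,
    crs: str = DEFAULT_CRS,
    removed_nodes: set[int] | None = None,
) -> None:
    feats = []
    for nid in sorted(network.nodes):
        x, y = network.nodes[nid]
        props = {"node_id": nid}
        if removed_nodes is not None:
            props["removed"] = nid in removed_nodes
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": props,
            }
        )
    for e in network.edges:
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [
                        list(network.nodes[e.node_a]),
                        list(network.nodes[e.node_b]),
                    ],
                },
                "properties": {
                    "edge_id": e.edge_id,
                    "node_a": e.node_a,
                    "node_b": e.node_b,
                    "length_m": e.length_m,
                    "road_class": e.road_class,
                },
            }
        )
    Path(path).write_text(json.dumps(_fc(feats, crs), sort_keys=True))


def read_network_geojson(path: str | Path) -> tuple[RoadNetwork, str]:
    doc = json.loads(Path(path).read_text())
    nodes: dict[int, tuple[float, float]] = {}
    edges: list[Edge] = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = feat["geometry"]
            props = feat.get("properties", {})
            if geom["type"] == "Point":
                x, y = geom["coordinates"]
                nodes[int(props["node_id"])] = (float(x), float(y))
            elif geom["type"] == "LineString":
                edges.append(
                    Edge(
                        int(props["edge_id"]),
                        int(props["node_a"]),
                        int(props["node_b"]),
                        float(props["length_m"]),
                        str(props["road_class"]),
                    )
                )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed network feature at index {i}: {exc}") from exc
    return RoadNetwork(nodes, edges), doc.get("crs_name", DEFAULT_CRS)


# --- facilities ------------------------------------------------------------


def write_facilities_geojson(
    facilities: FacilitySet, path: str | Path, crs: str = DEFAULT_CRS
) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [f.x, f.y]},
            "properties": {"facility_id": f.facility_id},
        }
        for f in facilities
    ]
    Path(path).write_text(json.dumps(_fc(feats, crs), sort_keys=True))


def read_facilities_geojson(path: str | Path) -> tuple[FacilitySet, str]:
    doc = json.loads(Path(path).read_text())
    facs = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            x, y = feat["geometry"]["coordinates"]
            facs.append(Facility(int(feat["properties"]["facility_id"]), float(x), float(y)))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed facility feature at index {i}: {exc}") from exc
    return FacilitySet(facs), doc.get("crs_name", DEFAULT_CRS)


# --- flood masks -----------------------------------------------------------


def write_flood_geojson(
    mask: FloodMask, path: str | Path, crs: str = DEFAULT_CRS, **properties
) -> None:
    geom = mask.geom if not mask.is_empty else MultiPolygon([])
    feat = {
        "type": "Feature",
        "geometry": mapping(geom),
        "properties": dict(properties),
    }
    Path(path).write_text(json.dumps(_fc([feat], crs), sort_keys=True))


def read_flood_geojson(path: str | Path) -> tuple[FloodMask, str]:
    doc = json.loads(Path(path).read_text())
    geoms = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            g = shape(feat["geometry"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed flood feature at index {i}: {exc}") from exc
        if not g.is_empty:
            if not isinstance(g, (Polygon, MultiPolygon)):
                raise ValueError(f"flood feature {i} is not polygonal: {g.geom_type}")
            geoms.append(g)
    if not geoms:
        return FloodMask.empty(), doc.get("crs_name", DEFAULT_CRS)
    from shapely.ops import unary_union

    return FloodMask(unary_union(geoms)), doc.get("crs_name", DEFAULT_CRS)


# --- Esri ASCII rasters ----------------------------------------------------


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = _NODATA) -> None:
    """Esri ASCII grid; NaN/inf sentinels map to the nodata value."""
    f = raster.frame
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = nodata
    header = (
        f"ncols {f.n_cols}\n"
        f"nrows {f.n_rows}\n"
        f"xllcorner {f.x0!r}\n"
        f"yllcorner {(f.y0 - f.n_rows * f.cell_m)!r}\n"
        f"cellsize {f.cell_m!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(
    path: str | Path, kind: str = "raw", nodata_as: float = np.nan
) -> Raster:
    """Read an Esri ASCII grid.

    ``kind`` chooses the container (and the sentinel nodata maps to):
    ``friction`` (NaN = impassable), ``population`` (0), ``time``
    (+inf = unreachable) or ``raw`` (``nodata_as``).
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    for i, line in enumerate(lines[:6]):
        try:
            key, val = line.split()
            header[key.lower()] = float(val)
        except ValueError as exc:
            raise ValueError(f"malformed ASCII grid header at line {i + 1}") from exc
    try:
        n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
        cell = header["cellsize"]
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + n_rows * cell
        nodata = header.get("nodata_value", _NODATA)
    except KeyError as exc:
        raise ValueError(f"ASCII grid header missing {exc}") from exc
    vals = np.loadtxt(lines[6:], dtype=float).reshape(n_rows, n_cols)
    mask = vals == nodata
    frame = GridFrame(x0, y0, cell, n_rows, n_cols)
    if kind == "friction":
        vals[mask] = np.nan
        return FrictionGrid(frame, vals)
    if kind == "population":
        vals[mask] = 0.0
        return PopulationGrid(frame, vals)
    if kind == "time":
        vals[mask] = np.inf
        return TimeGrid(frame, vals)
    vals[mask] = nodata_as
    return Raster(frame, vals)


# --- sidecar ---------------------------------------------------------------


def write_sidecar(path: str | Path, crs: str = DEFAULT_CRS, **meta) -> None:
    Path(path).write_text(json.dumps({"crs_name": crs, **meta}, sort_keys=True, indent=1))


def check_crs(*crs_names: str) -> str:
    """All inputs must share one CRS; never silently reproject."""
    names = {c for c in crs_names if c}
    if len(names) > 1:
        raise ValueError(f"CRS mismatch between inputs: {sorted(names)}")
    return names.pop() if names else DEFAULT_CRS
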