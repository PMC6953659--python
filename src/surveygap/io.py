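"""Plain-text I/O: GeoJSON (via shapely) and per-cell CSV tables."""

from __future__ import annotations

import json

import pandas as pd
from shapely.geometry import mapping, shape


def read_geojson(path):
    """Read a GeoJSON file; returns a list of (geometry, properties)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return [(shape(f["geometry"]), f.get("properties") or {}) for f in gj["features"]]
    if gj.get("type") == "Feature":
        return [(shape(gj["geometry"]), gj.get("properties") or {})]
    return [(shape(gj), {})]


def read_geojson_union(path):
    """Read a GeoJSON file and union all geometries (boundary input)."""
    import shapely

    geoms = [g for g, _ in read_geojson(path)]
    if not geoms:
        raise ValueError(f"no geometries in {path}")
    return shapely.union_all(geoms)


def write_geojson(path, geometries, properties=None):
    feats = []
    for k, geom in enumerate(geometries):
        props = properties[k] if properties is not None else {}
        feats.append({"type": "Feature", "geometry": mapping(geom), "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def grid_to_geojson(grid, path, land_only: bool = True):
    """Write cell polygons (with cell_id/ecoregion properties) as GeoJSON."""
    cells = grid.cells[grid.cells["land"]] if land_only else grid.cells
    geoms = [grid.cell_box(c) for c in cells["cell_id"]]
    props = cells.drop(columns=["lon", "lat"]).to_dict("records")
    write_geojson(path, geoms, props)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise ValueError(f"records CSV lacks columns: {sorted(missing)}")
    return df
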