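"""Thiessen-polygon (Voronoi) maps of sampling activity.

Each sampled grid cell contributes its centroid as a generator; the area of
the Voronoi polygon around it is a scale-free measure of local sampling
activity (large polygon = regionally sparse sampling).  The diagram is
computed in a Lambert azimuthal equal-area projection centered on the study
region so polygon areas are meaningful in km^2, then clipped to the land
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .grid import EARTH_RADIUS_KM

__all__ = ["LambertAzimuthalEqualArea", "VoronoiMap", "thiessen", "large_polygon_summary"]


class LambertAzimuthalEqualArea:
    """Spherical Lambert azimuthal equal-area projection (km units)."""

    def __init__(self, lon0: float, lat0: float, radius: float = EARTH_RADIUS_KM):
        self.lon0 = np.deg2rad(lon0)
        self.lat0 = np.deg2rad(lat0)
        self.R = radius

    def forward(self, lon, lat):
        lam = np.deg2rad(np.asarray(lon, float)) - self.lon0
        phi = np.deg2rad(np.asarray(lat, float))
        c = 1.0 + np.sin(self.lat0) * np.sin(phi) + np.cos(self.lat0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / c)
        x = self.R * k * np.cos(phi) * np.sin(lam)
        y = self.R * k * (np.cos(self.lat0) * np.sin(phi) - np.sin(self.lat0) * np.cos(phi) * np.cos(lam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, float) / self.R
        y = np.asarray(y, float) / self.R
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho == 0,
                self.lat0,
                np.arcsin(np.cos(c) * np.sin(self.lat0) + y * np.sin(c) * np.cos(self.lat0) / rho),
            )
            lam = np.where(
                rho == 0,
                0.0,
                np.arctan2(x * np.sin(c), rho * np.cos(self.lat0) * np.cos(c) - y * np.sin(self.lat0) * np.sin(c)),
            )
        return np.rad2deg(lam + self.lon0), np.rad2deg(phi)

    def project_geometry(self, geom):
        return shapely.transform(geom, lambda pts: np.column_stack(self.forward(pts[:, 0], pts[:, 1])))

    def unproject_geometry(self, geom):
        return shapely.transform(geom, lambda pts: np.column_stack(self.inverse(pts[:, 0], pts[:, 1])))


@dataclass
class VoronoiMap:
    """Voronoi tessellation of sampled-cell centroids, clipped to land.

    ``table`` has one row per generator with its lon/lat, polygon area in
    km^2, and any per-generator metadata passed in (e.g. ecoregion);
    ``polygons`` are the clipped shapely polygons in lon/lat coordinates;
    ``region_area_km2`` the clipped study-region area.
    """

    table: pd.DataFrame
    polygons: list
    region_area_km2: float
    projection: LambertAzimuthalEqualArea

    def check_conservation(self, rtol: float = 1e-3) -> bool:
        return abs(self.table["area_km2"].sum() - self.region_area_km2) <= rtol * self.region_area_km2


def thiessen(centroids: pd.DataFrame, boundary, metadata: pd.DataFrame = None) -> VoronoiMap:
    """Voronoi polygons of sampled-cell centroids within a boundary.

    Parameters
    ----------
    centroids : DataFrame with ``lon`` and ``lat`` columns (one row per
        sampled cell).
    boundary : shapely (Multi)Polygon in lon/lat; polygons are clipped to it.
    metadata : optional DataFrame aligned with ``centroids`` (e.g. the
        generating cell's ecoregion) carried through to the output table.
    """
    if len(centroids) == 0:
        raise ValueError("no sampled cells")
    lon = centroids["lon"].to_numpy(float)
    lat = centroids["lat"].to_numpy(float)

    cen = boundary.centroid
    proj = LambertAzimuthalEqualArea(cen.x, cen.y)
    px, py = proj.forward(lon, lat)
    pts = np.column_stack([px, py])
    region = proj.project_geometry(boundary)

    # Far-away frame generators make every real region finite; they sit far
    # outside the study region so they cannot steal clipped area.
    minx, miny, maxx, maxy = region.bounds
    span = max(maxx - minx, maxy - miny, 1e-6)
    cx, cy = (minx + maxx) / 2.0, (miny + maxy) / 2.0
    ang = np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
    frame = np.column_stack([cx + 100.0 * span * np.cos(ang), cy + 100.0 * span * np.sin(ang)])

    if len(pts) == 1:
        polys_proj = [region]
    else:
        vor = Voronoi(np.vstack([pts, frame]))
        polys_proj = []
        for k in range(len(pts)):
            reg = vor.regions[vor.point_region[k]]
            if -1 in reg or len(reg) == 0:
                raise RuntimeError("unbounded Voronoi region despite frame points")
            poly = Polygon(vor.vertices[reg])
            polys_proj.append(poly.intersection(region))

    areas = np.array([p.area for p in polys_proj])
    polygons = [proj.unproject_geometry(p) for p in polys_proj]
    table = pd.DataFrame({"lon": lon, "lat": lat, "area_km2": areas})
    if metadata is not None:
        meta = metadata.reset_index(drop=True)
        for col in meta.columns:
            table[col] = meta[col].to_numpy()
    return VoronoiMap(table=table, polygons=polygons, region_area_km2=region.area, projection=proj)


def large_polygon_summary(vmap: VoronoiMap, threshold_km2: float) -> dict:
    """Report on low-sampling-activity (large) polygons.

    Returns count, per-polygon areas (descending), max area, total area of
    large polygons, and — if the map carries an ``ecoregion`` column — the
    ecoregion of each large polygon's generating centroid.
    """
    t = vmap.table
    large = t[t["area_km2"] >= threshold_km2].sort_values("area_km2", ascending=False)
    out = {
        "threshold_km2": float(threshold_km2),
        "count": int(len(large)),
        "areas_km2": large["area_km2"].to_list(),
        "total_area_km2": float(large["area_km2"].sum()),
        "max_area_km2": float(t["area_km2"].max()) if len(t) else 0.0,
    }
    if "ecoregion" in t.columns:
        out["ecoregions"] = large["ecoregion"].to_list()
    return out
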