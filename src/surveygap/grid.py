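"""Analysis grid construction and per-cell aggregation.

The analysis lattice is a regular longitude/latitude grid at a fixed
arc-minute resolution, aligned to integer multiples of the cell size from
the bounding-box origin.  A cell is *land* iff its centroid falls inside the
study-region boundary; all per-cell assignment (records, range maps,
ecoregions) uses the same half-open cell intervals [west, east) x [south,
north) so that no point can belong to two cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPolygon, Polygon, box
from shapely.strtree import STRtree

EARTH_RADIUS_KM = 6371.0
KM_PER_DEGREE = np.pi * EARTH_RADIUS_KM / 180.0

#: canonical covariate column order (richness, accessibility, security)
COVARIATE_COLUMNS = [
    "richness",
    "elev_heterogeneity",
    "protected_pct",
    "road_km",
    "urban_pct",
    "pop_density",
    "homicide_rate",
]


@dataclass
class Grid:
    """Regular lon/lat lattice with land flags and optional ecoregion labels.

    Attributes
    ----------
    resolution : float
        Cell size in arc-minutes.
    west, south : float
        Lattice origin (degrees), snapped to integer multiples of the cell
        size.
    n_rows, n_cols : int
        Lattice dimensions (rows increase northward).
    cells : pandas.DataFrame
        One row per lattice cell with columns ``cell_id, row, col, lon, lat,
        area_km2, land`` and (once assigned) ``ecoregion``.  ``cell_id`` is
        dense ``0..n-1`` in row-major order.
    boundary : shapely geometry or None
        The study-region polygon the grid was built from.
    """

    resolution: float
    west: float
    south: float
    n_rows: int
    n_cols: int
    cells: pd.DataFrame
    boundary: object = field(default=None, repr=False)

    @property
    def cell_size_deg(self) -> float:
        return self.resolution / 60.0

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def land_mask(self) -> np.ndarray:
        return self.cells["land"].to_numpy()

    @property
    def land_ids(self) -> np.ndarray:
        return self.cells.loc[self.cells["land"], "cell_id"].to_numpy()

    @property
    def n_land(self) -> int:
        return int(self.cells["land"].sum())

    def locate(self, lon, lat) -> np.ndarray:
        """Map points to cell ids with half-open intervals; -1 if outside."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        cs = self.cell_size_deg
        col = np.floor((lon - self.west) / cs).astype(int)
        row = np.floor((lat - self.south) / cs).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(inside, row * self.n_cols + col, -1)
        return out

    def cell_box(self, cell_id: int) -> Polygon:
        cs = self.cell_size_deg
        row, col = divmod(int(cell_id), self.n_cols)
        w = self.west + col * cs
        s = self.south + row * cs
        return box(w, s, w + cs, s + cs)

    def boundary_polygon(self):
        """Study-region polygon: the stored boundary, else the bbox."""
        if self.boundary is not None:
            return self.boundary
        cs = self.cell_size_deg
        return box(
            self.west,
            self.south,
            self.west + self.n_cols * cs,
            self.south + self.n_rows * cs,
        )


def _cell_areas_km2(lat: np.ndarray, resolution: float) -> np.ndarray:
    """Spherical-rectangle area: R^2 * dlam * dphi * cos(lat_centroid)."""
    d = np.deg2rad(resolution / 60.0)
    return EARTH_RADIUS_KM**2 * d * d * np.cos(np.deg2rad(lat))


def build_grid(boundary, resolution: float = 5.0) -> Grid:
    """Build the analysis lattice over a study-region boundary.

    Parameters
    ----------
    boundary : shapely (Multi)Polygon in lon/lat degrees.
    resolution : float
        Cell size in arc-minutes (default 5').

    A cell is land iff its centroid lies inside ``boundary``.
    """
    if boundary is None or getattr(boundary, "is_empty", True):
        raise ValueError("boundary polygon is empty")
    if not boundary.is_valid:
        raise ValueError("boundary polygon is invalid; repair it before gridding")
    if resolution <= 0:
        raise ValueError("resolution must be positive arc-minutes")

    cs = resolution / 60.0
    minx, miny, maxx, maxy = boundary.bounds
    west = np.floor(minx / cs) * cs
    south = np.floor(miny / cs) * cs
    n_cols = int(np.ceil((maxx - west) / cs - 1e-12))
    n_rows = int(np.ceil((maxy - south) / cs - 1e-12))

    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    lon = west + (cols + 0.5) * cs
    lat = south + (rows + 0.5) * cs
    land = shapely.contains_xy(boundary, lon, lat)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_rows * n_cols),
            "row": rows,
            "col": cols,
            "lon": lon,
            "lat": lat,
            "area_km2": _cell_areas_km2(lat, resolution),
            "land": land,
        }
    )
    return Grid(resolution, west, south, n_rows, n_cols, cells, boundary)


def make_lattice_grid(
    n_rows: int,
    n_cols: int,
    resolution: float = 5.0,
    origin: tuple[float, float] = (-105.0, 20.0),
) -> Grid:
    """All-land rectangular grid (synthetic landscapes, toy fixtures)."""
    if n_rows * n_cols < 1:
        raise ValueError("grid must have at least one cell")
    cs = resolution / 60.0
    west, south = origin
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    lat = south + (rows + 0.5) * cs
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n_rows * n_cols),
            "row": rows,
            "col": cols,
            "lon": west + (cols + 0.5) * cs,
            "lat": lat,
            "area_km2": _cell_areas_km2(lat, resolution),
            "land": True,
        }
    )
    return Grid(resolution, west, south, n_rows, n_cols, cells)


def assign_ecoregions(grid: Grid, ecoregions: dict) -> Grid:
    """Label each land cell with the ecoregion whose polygon contains its
    centroid; unassigned land cells take the nearest ecoregion polygon."""
    land = grid.cells[grid.cells["land"]]
    lon = land["lon"].to_numpy()
    lat = land["lat"].to_numpy()
    labels = np.full(len(land), None, dtype=object)
    for name, geom in ecoregions.items():
        hit = shapely.contains_xy(geom, lon, lat)
        labels[hit] = name
    missing = np.flatnonzero(labels == None)  # noqa: E711
    if missing.size:
        names = list(ecoregions)
        geoms = [ecoregions[n] for n in names]
        pts = shapely.points(lon[missing], lat[missing])
        for k, pt in zip(missing, pts):
            dists = [g.distance(pt) for g in geoms]
            labels[k] = names[int(np.argmin(dists))]
    grid.cells.loc[grid.cells["land"], "ecoregion"] = labels
    return grid


# ---------------------------------------------------------------------------
# record assignment


def assign_records(records: pd.DataFrame, grid: Grid):
    """Aggregate occurrence records to grid cells.

    Parameters
    ----------
    records : DataFrame with columns ``species, lon, lat``.

    Returns
    -------
    cells : DataFrame indexed by land ``cell_id`` with ``record_count``,
        ``species_count`` (distinct species) and ``sampled`` columns.
    dropped : dict with counts of records outside the lattice and on
        non-land cells (reported, never fatal).
    """
    for col in ("species", "lon", "lat"):
        if col not in records.columns:
            raise ValueError(f"records table lacks required column {col!r}")
    lon = records["lon"].to_numpy(dtype=float)
    lat = records["lat"].to_numpy(dtype=float)
    if not (np.isfinite(lon).all() and np.isfinite(lat).all()):
        raise ValueError("records contain non-finite coordinates")

    ids = grid.locate(lon, lat)
    outside = ids < 0
    land_set = grid.land_mask
    nonland = ~outside & ~land_set[np.clip(ids, 0, None)]
    keep = ~outside & ~nonland

    land_ids = grid.land_ids
    out = pd.DataFrame(
        {"record_count": 0, "species_count": 0},
        index=pd.Index(land_ids, name="cell_id"),
    )
    if keep.any():
        sub = pd.DataFrame({"cell_id": ids[keep], "species": records["species"].to_numpy()[keep]})
        counts = sub.groupby("cell_id").size()
        nsp = sub.groupby("cell_id")["species"].nunique()
        out.loc[counts.index, "record_count"] = counts
        out.loc[nsp.index, "species_count"] = nsp
    out["sampled"] = out["record_count"] >= 1
    dropped = {"outside_grid": int(outside.sum()), "non_land": int(nonland.sum())}
    return out, dropped


# ---------------------------------------------------------------------------
# range maps and richness


def _in_range_mask(geom, grid: Grid, rule: str) -> np.ndarray:
    """Boolean mask over land cells for one species polygon."""
    land = grid.cells[grid.cells["land"]]
    if rule == "centroid":
        return shapely.contains_xy(geom, land["lon"].to_numpy(), land["lat"].to_numpy())
    if rule == "intersect":
        boxes = [grid.cell_box(c) for c in land["cell_id"]]
        tree = STRtree(boxes)
        hit = np.zeros(len(boxes), dtype=bool)
        hit[tree.query(geom, predicate="intersects")] = True
        return hit
    raise ValueError(f"unknown range rule {rule!r}")


def range_size(range_polygons: dict, grid: Grid, rule: str = "centroid"):
    """Count in-range land cells per species.

    Returns a DataFrame indexed by species with ``range_cells``; species with
    zero in-range cells are flagged (``excluded`` column) with a warning and
    should be dropped downstream.
    """
    rows = {}
    for sp, geom in range_polygons.items():
        if not geom.is_valid:
            raise ValueError(f"range polygon for {sp!r} is invalid")
        rows[sp] = int(_in_range_mask(geom, grid, rule).sum())
    out = pd.DataFrame({"range_cells": pd.Series(rows)})
    out.index.name = "species"
    out["excluded"] = out["range_cells"] == 0
    if out["excluded"].any():
        bad = list(out.index[out["excluded"]])
        warnings.warn(f"{len(bad)} species with empty gridded range excluded: {bad}")
    return out


def richness_overlay(range_polygons: dict, grid: Grid, rule: str = "centroid") -> pd.Series:
    """Per land cell, the number of species whose range contains it."""
    if not range_polygons:
        raise ValueError("need at least one species range polygon")
    land_ids = grid.land_ids
    richness = np.zeros(len(land_ids), dtype=int)
    for geom in range_polygons.values():
        richness += _in_range_mask(geom, grid, rule)
    return pd.Series(richness, index=pd.Index(land_ids, name="cell_id"), name="richness")


def species_sampled_cells(records: pd.DataFrame, grid: Grid) -> pd.Series:
    """Distinct sampled land cells per species (may exceed mapped range)."""
    ids = grid.locate(records["lon"].to_numpy(float), records["lat"].to_numpy(float))
    keep = (ids >= 0) & grid.land_mask[np.clip(ids, 0, None)]
    sub = pd.DataFrame({"species": records["species"].to_numpy()[keep], "cell_id": ids[keep]})
    out = sub.groupby("species")["cell_id"].nunique()
    out.name = "sampled_cells"
    return out


# ---------------------------------------------------------------------------
# covariates


def _segment_length_km(coords: np.ndarray) -> float:
    """Equirectangular polyline length, scaled by cos(mean latitude)."""
    if len(coords) < 2:
        return 0.0
    xy = np.asarray(coords, dtype=float)
    dlon = np.diff(xy[:, 0])
    dlat = np.diff(xy[:, 1])
    mlat = np.deg2rad(0.5 * (xy[:-1, 1] + xy[1:, 1]))
    dx = dlon * np.cos(mlat) * KM_PER_DEGREE
    dy = dlat * KM_PER_DEGREE
    return float(np.sum(np.hypot(dx, dy)))


def geodesic_length_km(geom) -> float:
    """Approximate length in km of a lon/lat LineString geometry."""
    if geom.is_empty:
        return 0.0
    if geom.geom_type == "LineString":
        return _segment_length_km(np.asarray(geom.coords))
    if geom.geom_type in ("MultiLineString", "GeometryCollection"):
        return sum(geodesic_length_km(g) for g in geom.geoms if g.geom_type.endswith("LineString"))
    return 0.0


def covariate_build(
    grid: Grid,
    elevation: pd.DataFrame | None = None,
    roads: list | None = None,
    urban=None,
    protected=None,
    population: list | None = None,
    homicide: list | None = None,
) -> pd.DataFrame:
    """Build the seven per-cell explanatory variables from raw layers.

    Parameters
    ----------
    elevation : DataFrame(lon, lat, value) of point samples (e.g. a DEM
        exported as a per-cell or finer table).  Heterogeneity is the
        max - min of samples whose centers fall in the cell; cells with no
        sample get 0 with a warning.
    roads : list of shapely LineStrings (lon/lat); road_km is the clipped
        length inside each cell.
    urban, protected : (Multi)Polygon or list of Polygons; the covariate is
        the percentage of the cell covered.
    population, homicide : list of (polygon, value) pairs; the covariate is
        the area-weighted mean of intersecting polygons' values.

    Richness is not built here: it comes from :func:`richness_overlay`.
    """
    land = grid.cells[grid.cells["land"]]
    idx = pd.Index(land["cell_id"].to_numpy(), name="cell_id")
    out = pd.DataFrame(index=idx)

    if elevation is not None:
        ids = grid.locate(elevation["lon"].to_numpy(float), elevation["lat"].to_numpy(float))
        het = pd.Series(0.0, index=idx)
        ok = ids >= 0
        sub = pd.DataFrame({"cell_id": ids[ok], "v": elevation["value"].to_numpy(float)[ok]})
        g = sub.groupby("cell_id")["v"]
        rng = (g.max() - g.min()).reindex(idx)
        n_empty = int(rng.isna().sum())
        if n_empty:
            warnings.warn(f"{n_empty} land cells have no elevation samples; heterogeneity set to 0")
        het.loc[rng.index] = rng.fillna(0.0)
        out["elev_heterogeneity"] = het

    cell_boxes = None

    def boxes():
        nonlocal cell_boxes
        if cell_boxes is None:
            cell_boxes = [grid.cell_box(c) for c in idx]
        return cell_boxes

    if roads is not None:
        tree = STRtree(list(roads))
        vals = np.zeros(len(idx))
        for k, b in enumerate(boxes()):
            for j in tree.query(b, predicate="intersects"):
                vals[k] += geodesic_length_km(roads[j].intersection(b))
        out["road_km"] = vals

    for name, layer in (("urban_pct", urban), ("protected_pct", protected)):
        if layer is None:
            continue
        if isinstance(layer, (Polygon, MultiPolygon)):
            geoms = [layer]
        else:
            geoms = list(layer)
        tree = STRtree(geoms)
        vals = np.zeros(len(idx))
        for k, b in enumerate(boxes()):
            hits = tree.query(b, predicate="intersects")
            if len(hits):
                inter = shapely.union_all([geoms[j].intersection(b) for j in hits])
                vals[k] = 100.0 * inter.area / b.area
        out[name] = vals

    for name, layer in (("pop_density", population), ("homicide_rate", homicide)):
        if layer is None:
            continue
        geoms = [g for g, _ in layer]
        values = np.array([v for _, v in layer], dtype=float)
        tree = STRtree(geoms)
        vals = np.full(len(idx), np.nan)
        for k, b in enumerate(boxes()):
            hits = tree.query(b, predicate="intersects")
            w = np.array([geoms[j].intersection(b).area for j in hits])
            if w.sum() > 0:
                vals[k] = np.average(values[hits], weights=w)
        if np.isnan(vals).any():
            warnings.warn(
                f"{int(np.isnan(vals).sum())} land cells intersect no {name} polygon; left as NaN"
            )
        out[name] = vals

    return out


# ---------------------------------------------------------------------------
# screening and standardization


def screen_and_standardize(
    cells: pd.DataFrame,
    columns: list[str] | None = None,
    threshold: float = 0.6,
):
    """Pearson correlation screen and z-standardization of covariates.

    Returns ``(table, corr, flagged)`` where ``table`` carries a ``z_<name>``
    column per covariate (mean 0, SD 1 with the n-1 denominator), ``corr``
    is the covariate correlation matrix over land cells, and ``flagged`` the
    list of pairs with |r| >= ``threshold``.
    """
    if columns is None:
        columns = [c for c in COVARIATE_COLUMNS if c in cells.columns]
    if len(cells) < 2:
        raise ValueError("need at least two cells to screen covariates")
    sub = cells[columns].astype(float)
    sd = sub.std(ddof=1)
    dead = sd.index[(sd == 0) | sd.isna()]
    if len(dead):
        raise ValueError(f"zero-variance covariate(s): {list(dead)}")
    corr = sub.corr()
    flagged = [
        (a, b, float(corr.loc[a, b]))
        for i, a in enumerate(columns)
        for b in columns[i + 1 :]
        if abs(corr.loc[a, b]) >= threshold
    ]
    out = cells.copy()
    for c in columns:
        out["z_" + c] = (sub[c] - sub[c].mean()) / sd[c]
    return out, corr, flagged


def destandardize(z: pd.Series, original: pd.Series) -> pd.Series:
    """Invert :func:`screen_and_standardize` for one column."""
    return z * original.std(ddof=1) + original.mean()
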