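"""Threat-change variables and priority survey areas.

Four per-cell threat variables describe projected environmental change by
the 2050s: change in mean annual temperature (deg C), change in annual
precipitation (mm), and percentage-point change in forest and cropland
cover.  Univariate spatial regressions relate record presence to each
threat; the priority map flags un-sampled cells whose composite threat
score (mean of the standardized threat magnitudes, oriented so larger is
worse) sits in the top fraction among un-sampled cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .icar import AdjacencyGraph, ICARRegression

__all__ = ["build_threats", "univariate_threat_car", "priority_map"]

THREAT_COLUMNS = ["delta_temp", "delta_precip", "delta_forest", "delta_farmland"]


def build_threats(current: pd.DataFrame, future: pd.DataFrame, grid=None) -> pd.DataFrame:
    """Per-cell future-minus-current threat deltas.

    ``current`` and ``future`` are co-registered per-cell tables with
    columns ``temp, precip, forest, farmland`` (cover columns as
    proportions in [0, 1] or as raw class areas, normalized here before
    differencing).  Cells missing from either table are flagged in the
    ``missing`` column and should be excluded from model fits.
    """
    idx = current.index.union(future.index)
    cur = current.reindex(idx)
    fut = future.reindex(idx)
    for df in (cur, fut):
        for col in ("temp", "precip", "forest", "farmland"):
            if col not in df.columns:
                raise ValueError(f"threat table lacks column {col!r}")

    def proportions(df):
        cover = df[["forest", "farmland"]].copy()
        mx = cover.to_numpy(float)
        if np.nanmax(mx) > 1.0 + 1e-9:  # class areas -> proportions of cell
            total = df.get("cell_area", cover.sum(axis=1))
            cover = cover.div(total, axis=0)
        if ((cover < -1e-9) | (cover > 1 + 1e-9)).any().any():
            raise ValueError("cover proportions outside [0, 1]")
        return cover

    cov_c, cov_f = proportions(cur), proportions(fut)
    out = pd.DataFrame(
        {
            "delta_temp": fut["temp"] - cur["temp"],
            "delta_precip": fut["precip"] - cur["precip"],
            "delta_forest": 100.0 * (cov_f["forest"] - cov_c["forest"]),
            "delta_farmland": 100.0 * (cov_f["farmland"] - cov_c["farmland"]),
        },
        index=idx,
    )
    out["missing"] = out[THREAT_COLUMNS].isna().any(axis=1)
    return out


def univariate_threat_car(
    presence,
    threat: pd.Series,
    graph: AdjacencyGraph,
    **icar_kwargs,
) -> pd.DataFrame:
    """Bernoulli-logit ICAR fit of record presence on one standardized
    threat variable; returns the coefficient summary row (posterior median,
    50%/95% credible intervals, credibly-nonzero flag)."""
    x = np.asarray(threat, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("threat variable has zero variance")
    xz = (x - x.mean()) / sd
    icar_kwargs.setdefault("family", "bernoulli-logit")
    model = ICARRegression(**icar_kwargs).fit(xz[:, None], np.asarray(presence, float), graph=graph)
    row = model.summary_.loc[["beta[0]"]].copy()
    row.index = [threat.name or "threat"]
    row["converged"] = model.converged_
    return row


def _zscore_or_zero(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def priority_map(cells: pd.DataFrame, threats: pd.DataFrame, top_fraction: float = 0.1) -> pd.DataFrame:
    """Flag un-sampled cells in the top fraction of composite threat.

    The composite score per cell is the mean of four standardized threat
    magnitudes: |delta_temp|, |delta_precip|, deforestation
    (-delta_forest clipped at 0) and farmland expansion (delta_farmland
    clipped at 0) — each z-scored over cells so the scale of any single
    raw threat is immaterial.  Priority cells are un-sampled cells whose
    score falls in the top ``top_fraction`` among un-sampled cells, ties
    broken by cell id.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0, 1)")
    idx = cells.index
    t = threats.reindex(idx)
    comp = np.column_stack(
        [
            _zscore_or_zero(np.abs(t["delta_temp"].to_numpy(float))),
            _zscore_or_zero(np.abs(t["delta_precip"].to_numpy(float))),
            _zscore_or_zero(np.clip(-t["delta_forest"].to_numpy(float), 0.0, None)),
            _zscore_or_zero(np.clip(t["delta_farmland"].to_numpy(float), 0.0, None)),
        ]
    ).mean(axis=1)
    out = pd.DataFrame({"sampled": cells["sampled"].to_numpy(bool), "threat_score": comp}, index=idx)
    out["priority"] = False
    unsampled = out.index[~out["sampled"]]
    k = int(np.floor(top_fraction * len(unsampled) + 1e-9))
    if k > 0 and len(unsampled):
        ranked = out.loc[unsampled].sort_values(
            ["threat_score"], ascending=False, kind="mergesort"
        )
        # mergesort is stable, so equal scores keep index (cell id) order
        out.loc[ranked.index[:k], "priority"] = True
    return out
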