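"""Randomization-calibrated ecoregion sampling-bias statistic.

For each ecoregion d the statistic compares the observed number of sampled
cells n_d against the count expected if the N sampled cells had been placed
at random over the land grid:

    Bias_d = (n_d - p_d N) / sqrt(p_d (1 - p_d) N),

where p_d is the expected fraction of random cells falling in ecoregion d,
estimated as the mean over replicate random draws (default 100 sets of N
distinct land cells).  Positive values indicate over-sampling of the
stratum, negative under-sampling.  A chi-squared test on observed versus
expected per-ecoregion counts (df = k - 1) assesses overall
representativeness at alpha = .05.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["estimate_p", "bias_d", "chisq_representativeness", "ecoregion_bias_table"]


def estimate_p(grid, N: int, n_reps: int = 100, seed: int = 0):
    """Randomization estimate of per-ecoregion expected sampling fractions.

    Each replicate draws ``N`` distinct land cells uniformly without
    replacement (a cell cannot be sampled twice) and tallies them per
    ecoregion.  Returns ``(p, counts)``: a Series of mean fractions indexed
    by ecoregion and the (n_reps, k) replicate count matrix.
    """
    land = grid.cells[grid.cells["land"]]
    if "ecoregion" not in land.columns or land["ecoregion"].isna().any():
        raise ValueError("grid land cells lack ecoregion labels")
    n_land = len(land)
    if N > n_land:
        raise ValueError(f"N={N} exceeds the {n_land} land cells")
    if N < 1:
        raise ValueError("N must be >= 1")
    eco = land["ecoregion"].to_numpy()
    regions = pd.unique(eco)
    region_idx = pd.Series(np.arange(len(regions)), index=regions)
    codes = region_idx[eco].to_numpy()

    rng = np.random.default_rng(seed)
    counts = np.empty((n_reps, len(regions)), dtype=int)
    for r in range(n_reps):
        draw = rng.choice(n_land, size=N, replace=False)
        counts[r] = np.bincount(codes[draw], minlength=len(regions))
    p = pd.Series(counts.mean(axis=0) / N, index=pd.Index(regions, name="ecoregion"), name="p_d")
    return p, counts


def bias_d(n_d: float, p_d: float, N: int) -> float:
    """Standardized over/under-sampling score for one ecoregion."""
    if not 0.0 < p_d < 1.0:
        raise ValueError("p_d must lie strictly between 0 and 1 (degenerate stratum)")
    if N < 1:
        raise ValueError("N must be >= 1")
    return (n_d - p_d * N) / np.sqrt(p_d * (1.0 - p_d) * N)


def chisq_representativeness(observed, expected):
    """Pearson chi-squared of observed vs expected per-ecoregion counts.

    Returns ``(chi2, df, p)`` with df = k - 1 and an upper-tail p-value.
    Expected counts below 1 trigger a validity warning.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected lengths differ")
    if (exp <= 0).any():
        raise ValueError("all expected counts must be > 0")
    if (exp < 1).any():
        warnings.warn("expected count < 1 in some stratum; chi-squared validity is doubtful")
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    df = len(obs) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def ecoregion_bias_table(
    grid,
    cell_table: pd.DataFrame,
    n_reps: int = 100,
    seed: int = 0,
    expected: str = "replicate-mean",
):
    """Full per-ecoregion bias analysis.

    Parameters
    ----------
    cell_table : output of :func:`surveygap.grid.assign_records` (indexed by
        land cell_id with a ``sampled`` column).
    expected : "replicate-mean" (default) uses p_d*N with p_d averaged over
        randomization replicates as the chi-squared expectation;
        "single-set" uses the counts of the first random set.

    Returns
    -------
    table : DataFrame indexed by ecoregion with n_d, p_d, bias_d.
    test : dict with chi2, df, p_value, N.
    """
    land = grid.cells[grid.cells["land"]].set_index("cell_id")
    sampled_ids = cell_table.index[cell_table["sampled"]]
    N = int(len(sampled_ids))
    if N == 0:
        raise ValueError("no sampled cells")
    p, counts = estimate_p(grid, N, n_reps=n_reps, seed=seed)
    eco_sampled = land.loc[sampled_ids, "ecoregion"]
    n_d = eco_sampled.value_counts().reindex(p.index).fillna(0).astype(int)
    table = pd.DataFrame({"n_d": n_d, "p_d": p})
    table["bias_d"] = [bias_d(row.n_d, row.p_d, N) for row in table.itertuples()]
    if expected == "replicate-mean":
        exp = p.to_numpy() * N
    elif expected == "single-set":
        exp = counts[0].astype(float)
    else:
        raise ValueError(f"unknown expected rule {expected!r}")
    chi2, df, pval = chisq_representativeness(n_d.to_numpy(), exp)
    return table, {"chi2": chi2, "df": df, "p_value": pval, "N": N}
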