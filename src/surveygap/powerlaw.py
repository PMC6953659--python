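"""Power-law model of sampling coverage versus range size by foraging guild.

For species s with range size x_s (grid cells in its mapped range) and
y_s sampled cells (distinct cells with at least one record), the model is
the power law y = a x^b, fit on log scale as an OLS linear model

    ln y = intercept + b * clr + guild offsets + guild x clr interactions,

where clr is ln(range size) centered at its mean and the edge-space guild
is the reference category.  The per-guild slope is the power-law exponent
b: b > 1 means wide-ranging species have proportionally better-covered
ranges; b < 1 the opposite.  Sequential (type-I) F-tests assess range
size, guild, and interaction in that order; Tukey-style pairwise guild
contrasts are evaluated at the centered mean of log range size.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

import statsmodels.api as sm

logger = logging.getLogger(__name__)

GUILD_ORDER = ("edge", "narrow", "open")  # reference first
_PAIRS = (("narrow", "edge"), ("open", "narrow"), ("open", "edge"))

__all__ = ["PowerLawGuildRegression", "fit_powerlaw", "tukey_guild_contrasts", "guild_slopes"]


class PowerLawGuildRegression(BaseEstimator):
    """OLS power-law fit of sampled cells on range size with guild terms.

    Parameters
    ----------
    contrast_method : {"mvt", "classic"}
        Adjustment for the pairwise guild contrasts: single-step
        multivariate-t (default, matches general-linear-hypothesis
        multiple-comparison machinery) or the classical studentized-range
        (Tukey HSD) table.
    min_per_guild : minimum species per guild required to fit.

    Attributes (after ``fit``)
    ----------
    params_, bse_ : coefficient estimates and standard errors
        (order: intercept, clr, guild offsets, guild x clr interactions).
    anova_ : sequential F table (term, df_num, df_den, F, p).
    contrasts_ : pairwise guild differences at centered log-range 0 with
        estimate, SE, t, adjusted p (labels like "N-E" = narrow - edge).
    slopes_ : per-guild exponent b with SE and 95% CI.
    classification_ : per guild, one of {"below 1",
        "not distinguishable from 1", "above 1"}.
    n_excluded_ : species dropped because sampled_cells = 0 (log undefined).
    """

    def __init__(self, contrast_method: str = "mvt", min_per_guild: int = 3):
        self.contrast_method = contrast_method
        self.min_per_guild = min_per_guild

    def fit(self, X: pd.DataFrame, y=None):
        """Fit the model.

        ``X`` is a species table with columns ``range_cells`` and ``guild``
        (and ``sampled_cells`` if ``y`` is not given); ``y`` optionally
        passes the sampled-cell counts separately.
        """
        df = pd.DataFrame(X).copy()
        if y is not None:
            df["sampled_cells"] = np.asarray(y)
        for col in ("range_cells", "guild", "sampled_cells"):
            if col not in df.columns:
                raise ValueError(f"species table lacks column {col!r}")
        bad_guilds = set(df["guild"]) - set(GUILD_ORDER)
        if bad_guilds:
            raise ValueError(f"unknown guild labels: {sorted(bad_guilds)}")

        keep = df["sampled_cells"] > 0  # log undefined at zero
        self.n_excluded_ = int((~keep).sum())
        if self.n_excluded_:
            logger.info("excluding %d species with zero sampled cells", self.n_excluded_)
        df = df[keep]
        counts = df["guild"].value_counts()
        for g in GUILD_ORDER:
            if counts.get(g, 0) < self.min_per_guild:
                raise ValueError(
                    f"guild {g!r} has {counts.get(g, 0)} usable species "
                    f"(need >= {self.min_per_guild})"
                )

        logx = np.log(df["range_cells"].to_numpy(float))
        self.center_ = float(logx.mean())
        clr = logx - self.center_
        logy = np.log(df["sampled_cells"].to_numpy(float))

        # design: intercept | clr | guild dummies (non-reference) | interactions
        dummies = {g: (df["guild"] == g).to_numpy(float) for g in GUILD_ORDER[1:]}
        cols = [np.ones(len(df)), clr]
        names = ["intercept", "clr"]
        for g in GUILD_ORDER[1:]:
            cols.append(dummies[g])
            names.append(f"guild[{g}]")
        for g in GUILD_ORDER[1:]:
            cols.append(dummies[g] * clr)
            names.append(f"clr:guild[{g}]")
        Xd = np.column_stack(cols)
        res = sm.OLS(logy, Xd).fit()
        self.names_ = names
        self.params_ = pd.Series(res.params, index=names)
        self.bse_ = pd.Series(res.bse, index=names)
        self.cov_ = pd.DataFrame(res.cov_params(), index=names, columns=names)
        self.df_resid_ = int(res.df_resid)
        self.resid_sd_ = float(np.sqrt(res.mse_resid))
        self.ssr_ = float(res.ssr)
        self._result_ = res
        self._y_ = logy
        self._X_ = Xd

        self.anova_ = self._sequential_anova(logy, Xd)
        self.contrasts_ = self._tukey_contrasts()
        self.slopes_ = self._guild_slopes()
        self.classification_ = {
            g: _classify(lo, hi)
            for g, lo, hi in zip(self.slopes_.index, self.slopes_["ci_lo"], self.slopes_["ci_hi"])
        }
        return self

    # -- pieces -------------------------------------------------------------

    def _sequential_anova(self, y, Xd) -> pd.DataFrame:
        """Type-I (sequential) F-tests: range size, guild, interaction."""
        blocks = [(0, 1), (1, 2), (2, 4), (4, 6)]  # intercept, clr, guild, interaction
        ssr_prev = float(np.sum((y - y.mean()) ** 2))
        rows = []
        cum = []
        labels = ["range_size", "guild", "interaction"]
        mse = self.ssr_ / self.df_resid_
        for (a, b), label in zip(blocks[1:], labels):
            cum = list(range(0, b))
            res = sm.OLS(y, Xd[:, cum]).fit()
            ss = max(ssr_prev - float(res.ssr), 0.0)  # guard fp round-off
            df_num = b - a
            if mse > 0:
                F = (ss / df_num) / mse
            else:  # perfect fit: no residual variation to test against
                F = 0.0 if ss == 0 else np.inf
            p = float(stats.f.sf(F, df_num, self.df_resid_))
            rows.append(
                {
                    "term": label,
                    "df_num": df_num,
                    "df_den": self.df_resid_,
                    "sum_sq": ss,
                    "F": F,
                    "p": p,
                }
            )
            ssr_prev = float(res.ssr)
        return pd.DataFrame(rows).set_index("term")

    def _contrast_vector(self, g1: str, g2: str) -> np.ndarray:
        """Adjusted-mean difference g1 - g2 at centered log-range 0 reduces
        to the difference of guild offsets (edge offset is 0)."""
        c = np.zeros(len(self.names_))
        for g, sign in ((g1, 1.0), (g2, -1.0)):
            if g != GUILD_ORDER[0]:
                c[self.names_.index(f"guild[{g}]")] = sign
        return c

    def _tukey_contrasts(self) -> pd.DataFrame:
        C = np.array([self._contrast_vector(a, b) for a, b in _PAIRS])
        est = C @ self.params_.to_numpy()
        V = C @ self.cov_.to_numpy() @ C.T
        se = np.sqrt(np.diag(V))
        t = est / se
        Rcor = V / np.outer(se, se)
        if self.contrast_method == "mvt":
            p_adj = _mvt_maxabs_sf(np.abs(t), Rcor, self.df_resid_)
        elif self.contrast_method == "classic":
            p_adj = stats.studentized_range.sf(np.abs(t) * np.sqrt(2.0), 3, self.df_resid_)
        else:
            raise ValueError(f"unknown contrast_method {self.contrast_method!r}")
        labels = [f"{a[0].upper()}-{b[0].upper()}" for a, b in _PAIRS]
        return pd.DataFrame(
            {"estimate": est, "se": se, "t": t, "p_adj": p_adj},
            index=pd.Index(labels, name="contrast"),
        )

    def _guild_slopes(self) -> pd.DataFrame:
        rows = {}
        tcrit = stats.t.ppf(0.975, self.df_resid_)
        for g in GUILD_ORDER:
            c = np.zeros(len(self.names_))
            c[self.names_.index("clr")] = 1.0
            if g != GUILD_ORDER[0]:
                c[self.names_.index(f"clr:guild[{g}]")] = 1.0
            b = float(c @ self.params_.to_numpy())
            se = float(np.sqrt(c @ self.cov_.to_numpy() @ c))
            rows[g] = {"b": b, "se": se, "ci_lo": b - tcrit * se, "ci_hi": b + tcrit * se}
        return pd.DataFrame(rows).T.loc[list(GUILD_ORDER)]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted sampled-cell counts (response scale)."""
        df = pd.DataFrame(X)
        clr = np.log(df["range_cells"].to_numpy(float)) - self.center_
        eta = np.full(len(df), self.params_["intercept"]) + self.params_["clr"] * clr
        for g in GUILD_ORDER[1:]:
            mask = (df["guild"] == g).to_numpy(float)
            eta += mask * self.params_[f"guild[{g}]"] + mask * clr * self.params_[f"clr:guild[{g}]"]
        return np.exp(eta)


def _classify(lo: float, hi: float) -> str:
    if hi < 1.0:
        return "below 1"
    if lo > 1.0:
        return "above 1"
    return "not distinguishable from 1"


def _mvt_maxabs_sf(tabs: np.ndarray, R: np.ndarray, df: int) -> np.ndarray:
    """Single-step adjusted p: P(max_k |T_k| >= t) under a central
    multivariate t with correlation R (QMC rectangle probability, fixed
    stream for reproducibility)."""
    # pairwise contrasts of k groups are linearly dependent -> singular R
    mvt = stats.multivariate_t(loc=np.zeros(len(R)), shape=R, df=df, allow_singular=True)
    out = np.empty(len(tabs))
    for i, t in enumerate(tabs):
        lo = np.full(len(R), -t)
        hi = np.full(len(R), t)
        rect = mvt.cdf(hi, lower_limit=lo, random_state=np.random.default_rng(2024))
        out[i] = min(1.0, max(0.0, 1.0 - float(rect)))
    return out


# ---------------------------------------------------------------------------
# functional wrappers


def fit_powerlaw(species: pd.DataFrame, **kwargs) -> PowerLawGuildRegression:
    """Fit the guild power-law model on a species table with columns
    ``range_cells, sampled_cells, guild``."""
    return PowerLawGuildRegression(**kwargs).fit(species)


def tukey_guild_contrasts(fit: PowerLawGuildRegression) -> pd.DataFrame:
    return fit.contrasts_


def guild_slopes(fit: PowerLawGuildRegression):
    return fit.slopes_, fit.classification_
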