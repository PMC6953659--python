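"""Bayesian spatial GLM with an intrinsic conditional autoregressive prior.

The model for cell :math:`i` is

.. math::

    g(E[y_i]) = \\alpha + x_i^\\top \\beta + \\phi_i,

with a Bernoulli (logit link) or Poisson (log link) likelihood.  The
spatial effects :math:`\\phi` carry Besag's intrinsic Gaussian CAR prior,
whose improper joint density is, up to a constant,

.. math::

    p(\\phi \\mid \\tau) \\propto \\tau^{(n-C)/2}
        \\exp\\Big(-\\frac{\\tau}{2} \\sum_{i \\sim j} (\\phi_i-\\phi_j)^2\\Big),

where the sum runs over graph edges and :math:`C` is the number of
connected components.  Each :math:`\\phi_i` given its neighbors is normal
with mean the neighbor average and variance :math:`1/(\\tau m_i)`.

Priors follow the noninformative setup commonly used for these models:
flat (improper uniform) on the intercept, N(0, 1000) on covariate
coefficients, and Gamma(0.001, 0.001) — mean 1, variance 1000 — on the
ICAR precision :math:`\\tau`.

Inference is Metropolis-within-Gibbs: :math:`\\tau` by its conjugate Gamma
full conditional; :math:`\\phi` by single-site random-walk Metropolis,
vectorized over graph-coloring classes (sites in one class share no edge,
so their full conditionals are mutually independent given the rest);
:math:`\\alpha` and :math:`\\beta` by adaptive random-walk Metropolis.
After every sweep :math:`\\phi` is re-centered to sum to zero within each
connected component (the identification constraint of the intrinsic
prior); on a connected graph the removed mean is absorbed into the
intercept so the linear predictor is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

__all__ = [
    "AdjacencyGraph",
    "build_adjacency",
    "lattice_adjacency",
    "icar_logpdf",
    "sample_icar",
    "ICARRegression",
    "fit_icar",
    "rhat",
    "mcse",
    "summarize",
]


# ---------------------------------------------------------------------------
# adjacency


@dataclass
class AdjacencyGraph:
    """Symmetric neighbor structure over a set of cells (graph nodes)."""

    n: int
    edges: np.ndarray  # (E, 2) int array, i < j
    node_ids: np.ndarray  # original cell ids, len n
    neighbors: list = field(repr=False, default=None)
    degrees: np.ndarray = None
    components: np.ndarray = None
    n_components: int = 0
    coloring: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        A = self.matrix()
        self.neighbors = [A.indices[A.indptr[i] : A.indptr[i + 1]] for i in range(self.n)]
        self.degrees = np.diff(A.indptr).astype(int)
        self.n_components, self.components = connected_components(A, directed=False)
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edges))
        col = nx.coloring.greedy_color(g, strategy="largest_first")
        self.coloring = np.array([col[i] for i in range(self.n)], dtype=int)

    def matrix(self) -> sparse.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix."""
        if len(self.edges):
            i, j = self.edges[:, 0], self.edges[:, 1]
            data = np.ones(2 * len(self.edges))
            A = sparse.coo_matrix(
                (data, (np.r_[i, j], np.r_[j, i])), shape=(self.n, self.n)
            )
        else:
            A = sparse.coo_matrix((self.n, self.n))
        return A.tocsr()

    def laplacian(self) -> np.ndarray:
        A = self.matrix().toarray()
        return np.diag(A.sum(1)) - A

    @property
    def isolated(self) -> np.ndarray:
        return np.flatnonzero(self.degrees == 0)


def build_adjacency(grid, subset=None, rule: str = "queen") -> AdjacencyGraph:
    """Queen (8-neighbor, default) or rook adjacency among a cell subset.

    ``grid`` is a :class:`surveygap.grid.Grid`; ``subset`` a set/array of
    cell ids (default: all land cells).
    """
    cells = grid.cells
    if subset is None:
        ids = grid.land_ids
    else:
        ids = np.asarray(sorted(subset), dtype=int)
        if ids.size == 0:
            raise ValueError("adjacency subset is empty")
    sub = cells.set_index("cell_id").loc[ids]
    return _adjacency_from_rowcol(sub["row"].to_numpy(), sub["col"].to_numpy(), ids, rule)


def lattice_adjacency(n_rows: int, n_cols: int, rule: str = "queen") -> AdjacencyGraph:
    """Adjacency of a full rectangular lattice in row-major order."""
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    return _adjacency_from_rowcol(rows, cols, np.arange(n_rows * n_cols), rule)


def _adjacency_from_rowcol(rows, cols, ids, rule) -> AdjacencyGraph:
    if rule == "queen":
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif rule == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(f"unknown adjacency rule {rule!r}")
    pos = {(r, c): k for k, (r, c) in enumerate(zip(rows, cols))}
    edges = []
    for k, (r, c) in enumerate(zip(rows, cols)):
        for dr, dc in offsets:
            j = pos.get((r + dr, c + dc))
            if j is not None and j > k:
                edges.append((k, j))
    edges = np.array(edges, dtype=int) if edges else np.empty((0, 2), dtype=int)
    return AdjacencyGraph(n=len(ids), edges=edges, node_ids=np.asarray(ids))


# ---------------------------------------------------------------------------
# intrinsic prior utilities


def pairwise_diff_quadform(phi: np.ndarray, graph: AdjacencyGraph) -> float:
    """sum over edges of (phi_i - phi_j)^2."""
    if len(graph.edges) == 0:
        return 0.0
    d = phi[graph.edges[:, 0]] - phi[graph.edges[:, 1]]
    return float(d @ d)


def icar_logpdf(phi: np.ndarray, graph: AdjacencyGraph, tau: float, normalized: bool = True):
    """Log-density of the intrinsic CAR prior.

    With ``normalized=True`` this is the proper density on the subspace
    orthogonal to the per-component constant vectors (where the prior is a
    degenerate Gaussian with precision tau*L):

        0.5 * sum_{lambda_k > 0} log(tau * lambda_k / (2 pi))
        - (tau/2) * phi' L phi.

    With ``normalized=False`` only the quadratic term is returned.
    """
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (graph.n,):
        raise ValueError("phi length does not match graph")
    quad = -0.5 * tau * pairwise_diff_quadform(phi, graph)
    if not normalized:
        return quad
    lam = np.linalg.eigvalsh(graph.laplacian())
    pos = lam[lam > 1e-10 * max(1.0, lam.max(initial=1.0))]
    return quad + 0.5 * float(np.sum(np.log(tau * pos / (2.0 * np.pi))))


def sample_icar(graph: AdjacencyGraph, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Exact draw from the intrinsic CAR prior on its proper subspace.

    Eigendecomposition of the graph Laplacian; the null space (one constant
    vector per connected component) is removed, so the draw sums to zero
    within every component.  Isolated nodes get phi = 0.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    lam, V = np.linalg.eigh(graph.laplacian())
    thr = 1e-10 * max(1.0, lam.max(initial=1.0))
    keep = lam > thr
    z = rng.standard_normal(int(keep.sum()))
    return V[:, keep] @ (z / np.sqrt(tau * lam[keep]))


# ---------------------------------------------------------------------------
# likelihoods (pointwise contributions; constants independent of eta dropped)


def _pointwise_loglik(family: str, y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    if family == "bernoulli-logit":
        # y*eta - log(1 + exp(eta)), stable for large |eta|
        return y * eta - np.logaddexp(0.0, eta)
    if family == "poisson-log":
        return y * eta - np.exp(eta)
    if family == "poisson-log-truncated":
        mu = np.exp(eta)
        # zero-truncated Poisson: subtract log(1 - exp(-mu))
        return y * eta - mu - np.log1p(-np.exp(-np.clip(mu, 1e-12, None)))
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# R-hat


def rhat(draws: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``draws`` has shape (chains, draws_per_chain).  Computed as
    sqrt((((n-1)/n) W + B/n) / W) with W the mean within-chain variance and
    B = n * Var(chain means); floored at 1 (the estimand is >= 1, values
    below arise only from the finite-sample correction).
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("R-hat needs at least two chains")
    m, n = draws.shape
    if n < 10:
        raise ValueError("R-hat needs at least 10 retained draws per chain")
    W = draws.var(axis=1, ddof=1).mean()
    B = n * draws.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    return max(1.0, float(np.sqrt(((n - 1) / n * W + B / n) / W)))


def mcse(draws: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean by batch means
    (batch length ~ sqrt(n) per chain, pooled across chains)."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = draws.shape
    b = max(1, int(np.sqrt(n)))
    nb = n // b
    batches = draws[:, : nb * b].reshape(m, nb, b).mean(axis=2).reshape(-1)
    return float(batches.std(ddof=1) / np.sqrt(len(batches)))


# ---------------------------------------------------------------------------
# estimator


class ICARRegression(BaseEstimator):
    """Spatial GLM with an intrinsic CAR random effect, fit by MCMC.

    Parameters
    ----------
    family : {"bernoulli-logit", "poisson-log", "poisson-log-truncated"}
        Likelihood and link.  The truncated variant models counts known to
        be >= 1 (cells selected because they have records).
    chains, iterations, burn_in, thin : MCMC schedule.  The reference
        schedule used for full analyses is 3 chains x 100,000 iterations,
        50,000 burn-in, thin 10 (:func:`reference_schedule`); the default
        here is a desk-scale schedule (3 x 5,000 / 2,500 / 5).
    coef_prior_var : prior variance of covariate coefficients (N(0, v)).
    tau_shape, tau_rate : Gamma prior on the ICAR precision.
    spatial : bool
        If False the spatial effect is disabled (phi = 0 throughout) and
        the model reduces to an ordinary Bayesian GLM.
    seed : int
        Seed for all chains (per-chain streams are spawned from it).

    Attributes
    ----------
    draws_ : dict with arrays ``alpha`` (chains, nd), ``beta``
        (chains, nd, k), ``tau`` (chains, nd).
    phi_mean_ : posterior mean spatial effect per cell.
    summary_ : DataFrame of posterior medians, 50%/95% credible intervals,
        R-hat and the credibly-nonzero flag.
    rhat_ : Series of R-hat per scalar parameter.
    converged_ : True iff all R-hat <= ``rhat_threshold``.
    """

    def __init__(
        self,
        family: str = "bernoulli-logit",
        chains: int = 3,
        iterations: int = 5000,
        burn_in: int = 2500,
        thin: int = 5,
        coef_prior_var: float = 1000.0,
        tau_shape: float = 0.001,
        tau_rate: float = 0.001,
        spatial: bool = True,
        store_phi: bool = False,
        rhat_threshold: float = 1.1,
        mode_moves: int = 16,
        seed: int = 0,
    ):
        self.family = family
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.coef_prior_var = coef_prior_var
        self.tau_shape = tau_shape
        self.tau_rate = tau_rate
        self.spatial = spatial
        self.store_phi = store_phi
        self.rhat_threshold = rhat_threshold
        self.mode_moves = mode_moves
        self.seed = seed

    # -- public API ---------------------------------------------------------

    def fit(self, X, y, graph: AdjacencyGraph = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        n, k = X.shape
        if y.shape != (n,):
            raise ValueError("X and y are not aligned")
        if self.spatial:
            if graph is None:
                raise ValueError("a spatial fit needs an adjacency graph")
            if graph.n != n:
                raise ValueError("graph nodes do not align with rows of X")
        if self.family == "bernoulli-logit" and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("bernoulli-logit needs binary y")
        if self.family.startswith("poisson") and ((y < 0).any() or (y % 1 != 0).any()):
            raise ValueError("poisson families need nonnegative integer y")
        if not self.burn_in < self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        _pointwise_loglik(self.family, y[:1], np.zeros(1))  # family validation

        # smoothest Laplacian eigenmodes for large-scale phi moves; the
        # single-site sweep handles rough modes, these handle the slow ones
        modes = None
        if self.spatial and self.mode_moves > 0 and n <= 4000:
            lam, V = np.linalg.eigh(graph.laplacian())
            thr = 1e-10 * max(1.0, lam.max(initial=1.0))
            pos = np.flatnonzero(lam > thr)
            take = pos[: min(self.mode_moves, len(pos))]
            modes = (lam[take], np.ascontiguousarray(V[:, take]))

        ss = np.random.SeedSequence(self.seed)
        child = ss.spawn(self.chains)
        tau_inits = [0.1, 1.0, 10.0]
        chains_out = []
        for c in range(self.chains):
            rng = np.random.default_rng(child[c])
            chains_out.append(
                _run_chain(
                    X,
                    y,
                    graph if self.spatial else None,
                    self.family,
                    self.iterations,
                    self.burn_in,
                    self.thin,
                    self.coef_prior_var,
                    self.tau_shape,
                    self.tau_rate,
                    tau_inits[c % len(tau_inits)],
                    self.store_phi,
                    modes,
                    rng,
                )
            )

        nd = len(chains_out[0]["alpha"])
        self.n_features_in_ = k
        self.draws_ = {
            "alpha": np.stack([c["alpha"] for c in chains_out]),
            "beta": np.stack([c["beta"] for c in chains_out]),
            "tau": np.stack([c["tau"] for c in chains_out]),
        }
        if self.store_phi and self.spatial:
            self.draws_["phi"] = np.stack([c["phi"] for c in chains_out])
        self.phi_mean_ = (
            np.mean([c["phi_mean"] for c in chains_out], axis=0) if self.spatial else np.zeros(n)
        )
        self.n_draws_per_chain_ = nd

        names = ["alpha"] + [f"beta[{j}]" for j in range(k)]
        mats = [self.draws_["alpha"]] + [self.draws_["beta"][:, :, j] for j in range(k)]
        if self.spatial:
            names.append("tau")
            mats.append(self.draws_["tau"])
        self.rhat_ = pd.Series({nm: rhat(m) for nm, m in zip(names, mats)})
        self.converged_ = bool((self.rhat_ <= self.rhat_threshold).all())
        self.summary_ = summarize(self)
        return self

    def predict(self, X):
        """Posterior-mean response at new covariates (no spatial effect)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "draws_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        a = self.draws_["alpha"].reshape(-1)
        b = self.draws_["beta"].reshape(-1, self.n_features_in_)
        eta = a[None, :] + X @ b.T
        if self.family == "bernoulli-logit":
            return (1.0 / (1.0 + np.exp(-eta))).mean(axis=1)
        return np.exp(eta).mean(axis=1)


def reference_schedule() -> dict:
    """The full MCMC schedule used for complete analyses."""
    return {"chains": 3, "iterations": 100_000, "burn_in": 50_000, "thin": 10}


def fit_icar(y, X, graph: AdjacencyGraph, **kwargs) -> ICARRegression:
    """Functional wrapper: fit an :class:`ICARRegression` and return it."""
    return ICARRegression(**kwargs).fit(X, y, graph=graph)


def summarize(fit: ICARRegression) -> pd.DataFrame:
    """Coefficient table: posterior median, 50% and 95% credible intervals,
    R-hat, and a credibly-nonzero flag (95% interval excludes 0)."""
    rows = {}
    k = fit.n_features_in_
    series = {"alpha": fit.draws_["alpha"].reshape(-1)}
    for j in range(k):
        series[f"beta[{j}]"] = fit.draws_["beta"][:, :, j].reshape(-1)
    if fit.spatial:
        series["tau"] = fit.draws_["tau"].reshape(-1)
    for nm, d in series.items():
        q = np.percentile(d, [2.5, 25, 50, 75, 97.5])
        rows[nm] = {
            "median": q[2],
            "q25": q[1],
            "q75": q[3],
            "q2.5": q[0],
            "q97.5": q[4],
            "rhat": fit.rhat_[nm],
            "nonzero": bool(q[0] > 0 or q[4] < 0),
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# sampler internals


def _run_chain(
    X,
    y,
    graph,
    family,
    iterations,
    burn_in,
    thin,
    coef_prior_var,
    tau_shape,
    tau_rate,
    tau_init,
    store_phi,
    modes,
    rng,
):
    n, k = X.shape
    spatial = graph is not None

    alpha = float(rng.normal(0.0, 1.0))
    beta = rng.normal(0.0, 1.0, size=k)
    tau = float(tau_init)
    phi = np.zeros(n)

    eta_fixed = alpha + X @ beta
    eta = eta_fixed + phi
    ll = _pointwise_loglik(family, y, eta)

    # proposal scales, adapted during burn-in toward ~0.44 acceptance
    s_coef = np.full(k + 1, 0.3)  # [alpha, beta...]
    s_phi = 0.5
    s_scale = 0.3
    acc_coef = np.zeros(k + 1)
    acc_phi = 0.0
    acc_scale = 0.0
    n_phi_prop = 0
    adapt_every = 100
    if modes is not None:
        mode_lam, mode_V = modes
        n_modes = len(mode_lam)
        s_mode = np.full(n_modes, 0.5)
        acc_mode = np.zeros(n_modes)

    if spatial:
        A = graph.matrix()
        deg = graph.degrees.astype(float)
        colors = [np.flatnonzero(graph.coloring == c) for c in range(graph.coloring.max() + 1)]
        colors = [c[deg[c] > 0] for c in colors]  # isolated nodes keep phi = 0
        comp = graph.components
        n_comp = graph.n_components
        comp_sizes = np.bincount(comp, minlength=n_comp).astype(float)
        rank = n - n_comp  # rank of the Laplacian

    n_retained = (iterations - burn_in) // thin
    out = {
        "alpha": np.empty(n_retained),
        "beta": np.empty((n_retained, k)),
        "tau": np.empty(n_retained),
    }
    if store_phi and spatial:
        out["phi"] = np.empty((n_retained, n))
    phi_sum = np.zeros(n)
    kept = 0

    for it in range(iterations):
        # --- alpha, beta: random-walk Metropolis, one coordinate at a time
        for j in range(k + 1):
            step = s_coef[j] * rng.standard_normal()
            if j == 0:
                eta_new = eta + step
                dprior = 0.0  # improper flat prior
            else:
                b = j - 1
                eta_new = eta + step * X[:, b]
                new_b = beta[b] + step
                dprior = -(new_b**2 - beta[b] ** 2) / (2.0 * coef_prior_var)
            ll_new = _pointwise_loglik(family, y, eta_new)
            if np.log(rng.random()) < ll_new.sum() - ll.sum() + dprior:
                if j == 0:
                    alpha += step
                else:
                    beta[j - 1] += step
                eta = eta_new
                ll = ll_new
                acc_coef[j] += 1

        if spatial:
            # --- phi: single-site RW Metropolis, vectorized per color class
            for idx in colors:
                nbr_sum = A @ phi
                cur = phi[idx]
                prop = cur + s_phi * rng.standard_normal(len(idx))
                eta_prop = eta[idx] + (prop - cur)
                d_ll = _pointwise_loglik(family, y[idx], eta_prop) - ll[idx]
                m = deg[idx]
                mean_nbr = nbr_sum[idx] / m
                d_prior = -0.5 * tau * m * ((prop - mean_nbr) ** 2 - (cur - mean_nbr) ** 2)
                accept = np.log(rng.random(len(idx))) < d_ll + d_prior
                if accept.any():
                    ai = idx[accept]
                    phi[ai] = prop[accept]
                    eta[ai] = eta_prop[accept]
                    ll[ai] = _pointwise_loglik(family, y[ai], eta[ai])
                acc_phi += accept.sum()
                n_phi_prop += len(idx)

            # --- large-scale eigenmode moves: phi' = phi + d * v_j
            # (L v_j = lam_j v_j makes the prior change closed-form)
            if modes is not None:
                for j in range(n_modes):
                    d = s_mode[j] * rng.standard_normal()
                    v = mode_V[:, j]
                    cj = v @ phi
                    eta_new = eta + d * v
                    ll_new = _pointwise_loglik(family, y, eta_new)
                    d_prior = -0.5 * tau * mode_lam[j] * (2.0 * d * cj + d * d)
                    if np.log(rng.random()) < ll_new.sum() - ll.sum() + d_prior:
                        phi += d * v
                        eta = eta_new
                        ll = ll_new
                        acc_mode[j] += 1

            # --- tau: conjugate Gamma full conditional (centered step)
            quad = pairwise_diff_quadform(phi, graph)
            tau = rng.gamma(tau_shape + 0.5 * rank, 1.0 / (tau_rate + 0.5 * quad))

            # --- interweaved non-centered tau step: hold u = sqrt(tau)*phi
            # fixed, move log tau, rescale phi = u/sqrt(tau').  In (u, tau)
            # coordinates the intrinsic prior is tau-free, so the ratio is
            # likelihood x Gamma prior x Jacobian — this walks along the
            # (phi-amplitude, tau) funnel that traps the centered sampler.
            dlt = s_scale * rng.standard_normal()
            tau_new = tau * np.exp(dlt)
            c = np.sqrt(tau / tau_new)
            eta_new = eta + (c - 1.0) * phi
            ll_new = _pointwise_loglik(family, y, eta_new)
            dprior = tau_shape * dlt - tau_rate * (tau_new - tau)  # Gamma(log-scale)
            if np.log(rng.random()) < ll_new.sum() - ll.sum() + dprior:
                tau = tau_new
                phi *= c
                eta = eta_new
                ll = ll_new
                acc_scale += 1

            # --- recenter phi per component; absorb the (size-weighted)
            # overall level into the improper intercept
            means = np.bincount(comp, weights=phi, minlength=n_comp) / comp_sizes
            shift = means[comp]
            phi -= shift
            overall = float(comp_sizes @ means / n)
            alpha += overall
            eta = eta - shift + overall
            ll = _pointwise_loglik(family, y, eta)

        # --- adaptation (burn-in only)
        if it < burn_in and (it + 1) % adapt_every == 0:
            rate = acc_coef / adapt_every
            s_coef *= np.exp(np.clip(rate - 0.44, -0.5, 0.5))
            acc_coef[:] = 0
            if spatial and n_phi_prop:
                rate_p = acc_phi / n_phi_prop
                s_phi *= np.exp(np.clip(rate_p - 0.44, -0.5, 0.5))
                acc_phi = 0.0
                n_phi_prop = 0
                s_scale *= np.exp(np.clip(acc_scale / adapt_every - 0.3, -0.5, 0.5))
                acc_scale = 0.0
                if modes is not None:
                    s_mode *= np.exp(np.clip(acc_mode / adapt_every - 0.44, -0.5, 0.5))
                    acc_mode[:] = 0.0

        if it >= burn_in and (it - burn_in) % thin == 0:
            out["alpha"][kept] = alpha
            out["beta"][kept] = beta
            out["tau"][kept] = tau
            if store_phi and spatial:
                out["phi"][kept] = phi
            phi_sum += phi
            kept += 1

    out["phi_mean"] = phi_sum / max(kept, 1)
    out["diag"] = {
        "s_coef": s_coef.copy(),
        "s_phi": s_phi,
        "s_scale": s_scale if spatial else None,
        "s_mode": s_mode.copy() if modes is not None else None,
    }
    return out
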