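# Methods

This note documents the statistical machinery behind `surveygap`: the
models and their assumptions, the default parameters and why they were
chosen, what the synthetic generator does and does not emulate, numerical
choices, and known limitations.

## Gridding

The analysis lattice is a regular longitude/latitude grid at a fixed
arc-minute resolution (default 5′), aligned to integer multiples of the
cell size from the bounding-box origin. Assignment rules, chosen for
determinism:

- A cell is **land** iff its centroid lies inside the study-region
  boundary; the same centroid rule labels cells with ecoregions and
  decides range-map membership (an any-intersection alternative sits
  behind `rule="intersect"`). Centroid-in-polygon gives every cell exactly
  one label with no area-threshold ambiguity.
- Points map to cells through half-open intervals `[west, east) ×
  [south, north)`, so a record on an interior edge belongs to exactly one
  cell and re-gridding is idempotent and order-independent.
- Cell areas use the spherical-rectangle formula `R²·Δλ·Δφ·cos(lat)` with
  R = 6,371 km (≈ 85.9 km² for a 5′ cell at the equator, ~78–82 km² at
  Mexican latitudes).

Covariate construction: elevational heterogeneity is max − min of
elevation samples whose centers fall in the cell (0 with a warning if a
cell has no samples); road density is clipped polyline length in km under
an equirectangular metric; urban and protected percentages are planar
area fractions of the cell box (exact within a cell, where the cos-lat
scale factor is effectively constant); population density and homicide
rate attach by area-weighted means of intersecting polygons (homicide is
a state-level metric, so cells straddling states get the weighted mean).
Covariates are screened for pairwise Pearson |r| ≥ 0.6 and z-standardized
with the n−1 denominator before model fitting.

## Sampling-activity map

Thiessen/Voronoi polygons of sampled-cell centroids are computed with
scipy's planar Voronoi in a spherical Lambert azimuthal equal-area
projection centered on the region centroid (so km² areas are meaningful),
made finite by a ring of far-away frame generators (100× the region
diameter — far enough that no frame cell intersects the region), then
clipped to the land boundary. Tessellation conservation (areas summing to
the region area within 0.1%) and agreement with a nearest-centroid
rasterization oracle are enforced by tests.

## Ecoregion bias statistic

`Bias_d = (n_d − p_d N)/sqrt(p_d (1 − p_d) N)` is a z-like score of the
observed sampled-cell count per ecoregion against a uniform-sampling
null. `p_d` is estimated by randomization: 100 replicate draws of N
distinct land cells (without replacement — a cell cannot be sampled
twice), averaged per ecoregion. The chi-squared representativeness test
compares observed counts to `p_d·N` with df = k − 1 (a single-random-set
expectation is available behind `expected="single-set"`). Under the null
the score has mean ≈ 0 and variance slightly below 1 because
without-replacement draws are underdispersed relative to the binomial;
the deflation factor is ≈ (1 − N/n_cells), so the chi-squared test is
near-nominal only when the sampling fraction is small. The calibration test
therefore uses a landscape with a ~2% fraction; at the ~9% fraction of
the default study conditions the test is mildly conservative (a property
of the method, not of this implementation).

## Taxonomic bias (guild power law)

`ln y = intercept + b·clr + guild + guild:clr`, with `clr` the natural
log of range size centered at its mean and edge-space foragers the
reference guild. Natural logs are used because the exponent — the
quantity of interest — is invariant to the log base. Species with zero
sampled cells are excluded (log undefined) and counted. Sequential
(type-I) F-tests enter range size, guild, interaction in that order and
are verified against brute-force nested-model sums of squares. Guild
contrasts are evaluated at centered log-range 0, where they reduce to
intercept differences; adjusted p-values use the single-step
multivariate-t rectangle probability (QMC with a fixed stream; the
pairwise-contrast correlation matrix is singular by construction and is
handled as such), with the classical studentized-range table behind
`contrast_method="classic"`. Per-guild exponents are linear combinations
of the base slope and interaction terms with t-based 95% CIs; each guild
is classified "below 1" / "not distinguishable from 1" / "above 1" by
whether the CI excludes 1.

On perfect (zero-residual) fits the sequential F statistic is 0/0; the
implementation clamps round-off-negative sums of squares to zero and
reports F = 0 when both the term's SS and the MSE vanish.

## Spatial ICAR regression

Model: `g(E[y_i]) = α + x_i'β + φ_i` with Bernoulli-logit (presence over
all land cells) or Poisson-log (record counts over sampled cells; a
zero-truncated Poisson variant is available since sampled cells have
counts ≥ 1, default off). φ carries Besag's intrinsic CAR prior over
queen (8-neighbor) adjacency — rook available — whose joint improper
density is `τ^{(n−C)/2} exp(−τ/2 Σ_{i~j}(φ_i−φ_j)²)` with C the number of
connected components. Priors: improper flat on α, N(0, 1000) on β, and
Gamma(shape 0.001, rate 0.001) on τ (moment-matching a mean of 1 and
variance of 1,000).

Sampler (all written here, no external engine):

- **τ** by its conjugate Gamma full conditional, shape `0.001 + (n−C)/2`,
  rate `0.001 + ½Σ(φ_i−φ_j)²` — verified against brute-force grid
  integration of the joint density on a 4-node cycle.
- **φ** by single-site random-walk Metropolis, vectorized over greedy
  graph-coloring classes (no two sites in a class share an edge, so their
  full conditionals are mutually independent given the rest); plus
  large-scale moves along the smoothest Laplacian eigenmodes (for modes,
  `Lv = λv` makes the prior change closed-form), which address the slow
  mixing of smooth field components under purely local updates.
- **τ–φ interweaving**: after the conjugate update, a non-centered step
  holds `u = √τ·φ` fixed and moves log τ by Metropolis (rescaling φ
  accordingly). In (u, τ) coordinates the intrinsic prior is τ-free, so
  the acceptance ratio involves only the likelihood, the Gamma prior and
  the log-scale Jacobian. This traverses the (field-amplitude, τ) funnel
  that otherwise traps the centered sampler (τ effective sample sizes
  rise from single digits to hundreds at the desk-scale schedule).
- **α, β** by per-coordinate adaptive random-walk Metropolis
  (Robbins-Monro-style scale adaptation toward 0.44 acceptance during
  burn-in only, frozen afterwards, so the retained chain is a fixed
  Markov kernel).
- After each sweep φ is re-centered to sum to zero within each connected
  component (the identification constraint of the intrinsic prior); the
  size-weighted overall level is absorbed into the improper intercept, so
  on a connected graph the linear predictor is unchanged. Isolated nodes
  carry φ = 0.

Chains start overdispersed (β jittered N(0,1), τ ∈ {0.1, 1, 10}).
Schedules: the reference schedule is 3 chains × 100,000 iterations,
50,000 burn-in, thinned by 10 (`reference_schedule()`); the default is a
desk-scale 3 × 5,000 / 2,500 / 5, which the calibration studies below
were run at. Convergence is summarized by the classic potential scale
reduction factor `sqrt(((n−1)/n·W + B/n)/W)` per scalar parameter,
floored at 1 (the estimand is ≥ 1; values below 1 arise only from the
finite-sample correction), with fits flagged non-converged above 1.1.

Correctness evidence encoded in the test suite: the ICAR log-density
matches a dense degenerate-Gaussian evaluation through the Laplacian
pseudo-inverse (≤ 6 nodes, 1e-8); with the spatial effect disabled the
chain means match an independent importance-sampling evaluation of the
exact posterior and the IRLS ML logistic fit (up to the genuine O(1/n)
posterior-mean/MLE offset, which importance sampling confirms is a
property of the posterior, not of the sampler); on model-generated
400-cell Bernoulli data the 95% credible intervals cover the generating
coefficients at ≈ 93% over 20 replicates.

**Known limitation (prior impropriety).** With a single Bernoulli trial
per cell, the Bernoulli-logit ICAR posterior under the Gamma(0.001,
0.001) precision prior is effectively improper: as τ → 0 the field is
unconstrained, any presence pattern can be matched exactly (complete
separation), and β reverts to its diffuse prior. An efficient sampler
will find this region on weakly informative datasets (e.g. very sparse
presence over smooth covariates) — runs there end with large R-hat and
the non-convergence flag, which should be taken at face value. Poisson
count likelihoods, better-balanced presence data, or a weakly informative
τ prior avoid the issue; the default priors are kept as stated because
they are the model's specification, and the acceptance studies evaluate
coefficient recovery in the identified regime.

## Threats and prioritization

Threat deltas are per-cell future-minus-current differences (2050s
horizon): temperature (°C), precipitation (mm), forest and farmland cover
(percentage points, proportions computed before differencing). Univariate
presence-vs-threat fits reuse the ICAR engine with a single standardized
covariate and use *signed* change; the composite priority score instead
uses harm-oriented magnitudes — |Δtemp|, |Δprecip|, deforestation
(−Δforest clipped at 0), farmland expansion (Δfarmland clipped at 0) —
each z-scored (so affine rescaling of any raw threat is absorbed) and
averaged. Priority cells are un-sampled cells in the top fraction
(default 10%) of the composite among un-sampled cells; ties break by cell
id, and the priority set is nested as the fraction grows. The
identification of priority areas as "under-surveyed ∧ high projected
change" is operationalized here as this composite-score rule; the
fraction is configurable.

## Synthetic landscape generator

The generator emulates the structure of a national presence-only
occurrence database at desk scale, with every generating parameter
returned as ground truth:

- **Landscape**: default 30 × 30 all-land grid of 5′ cells (900 cells ≈
  1/29 of the ~25.8k-cell national grid that motivates the pipeline),
  partitioned into 7 contiguous ecoregions by multi-source random BFS
  from random seed cells. Seven covariates are white noise smoothed by
  repeated 3 × 3 neighbor averaging (10 passes), scaled to plausible
  units; spatial autocorrelation is verified by brute-force Moran's I.
- **Species pool**: default 134 species; range sizes log-uniform between
  1 cell and the grid size; ranges grown as connected blobs by uniform
  random frontier expansion (contiguous, like range polygons); guilds
  drawn from the mix (0.20 open, 0.35 edge, 0.45 narrow — narrow-space
  foragers dominate, as in the bat fauna this emulates).
- **Records**: per-cell log intensity `α + x'β + φ` with φ an exact ICAR
  draw at τ = 1 (eigendecomposition of the graph Laplacian with the null
  space removed — exact sampling on the improper prior's proper
  subspace); per-(species, cell) counts Poisson with guild-specific
  detection multipliers (0.5/0.75/1.0 for open/edge/narrow, encoding that
  narrow-space foragers are most easily captured), optionally negative
  binomial via an overdispersion knob (no empirical default exists for
  per-cell dispersion, hence Poisson). α defaults to −5.2, calibrated
  once so that roughly one cell in ten is sampled — the sparse-coverage
  regime (9% sampled) the pipeline is meant to diagnose. Record
  coordinates are jittered uniformly within the generating cell so each
  record re-grids to it exactly.
- **Calibrated-detectability mode** (`b_target`): to impose a known
  per-guild power-law exponent, each in-range cell of species s yields a
  record with uniform probability `min(1, a·s^(b−1))`, making
  E[sampled cells] = `a·s^b` exact for a ≤ 1 and b ≤ 1 (an
  intensity-weighted variant was rejected because probability clipping in
  high-intensity cells attenuates b near 1).
- **Threat surfaces**: smooth current fields for temperature,
  precipitation, forest and farmland, with future counterparts adding
  spatially structured warming, precipitation change and forest-to-
  farmland conversion, scaled ×1 under "business-as-usual" and ×0.4 under
  "sustainable".

What it deliberately does **not** emulate: museum-record duplication,
georeferencing error, taxonomic misidentification, coastline/irregular
land masks, or within-cell habitat structure. Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
assumed generating process, not robustness to those real-data artifacts.

## Test and acceptance problem sizes

Desk-scale sizes were chosen so the full suite exercises every stage in
minutes: landscapes of 400–10,000 cells, pools of 60–500 species, MCMC at
the 3 × 5,000 schedule, 20-replicate coverage studies, and 200-replicate
calibration studies. `scripts/acceptance.py` runs the default 900-cell
study end to end; all randomness derives from `--seed` and repeated runs
are byte-identical. The power analysis of the guild contrast uses the
residual SD implied by study-scale contrast standard errors (σ ≈ 0.95)
and validates the simulated detection rate against the exact
noncentral-t power for the design.
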