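# Methods

This note documents the models implemented in `tcimpact`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Study design and panel construction

Each tropical cyclone (TC) is analyzed as a quasi-experiment. A county is
*treated* by a storm when its maximum sustained windspeed at the population
mean center reaches gale force, **17.4 m/s** (boundary inclusive); all other
counties are potential controls. The study period is ten contiguous two-week
intervals. The final interval — the treatment period — runs from 2 days
before to 11 days after the storm's first US approach; the nine baseline
intervals are anchored backwards from it, so the panel opens 128 days before
first approach. Anchoring on the treatment interval is deliberate: its
definition is the most precise element of the design, and a naive
"129 days before to 11 days after" span covers 141 days, one more than the
10 × 14 the aggregation requires.

Eligibility rules, applied per storm and in this order (the exclusion log
records the first rule that fires): population below 100; five or fewer
events of **any** studied outcome over the study period (one analytic set
per storm, shared across outcomes); for controls, centroid more than
150 miles from every retained treated county (haversine, Earth radius
6371 km; 150 mi = 241.402 km). A storm qualifies when it has at least one
treated county, at least 20 counties total, and at least 5 controls.
Rows are ordered treated-first, each block sorted by county id, so
reconstruction from permuted inputs is bit-identical.

Missing days inside the study period are a hard error by default
(`missing="zero"` is available but silent zero-filling biases baseline
trends, so it is opt-in). Population offsets are constant per county unless
a time-varying vector is supplied; at a 20-week horizon administrative
denominators are effectively static.

## Causal model

For each storm, counts at untreated cells follow

log E[Y_it(0)] = α + γ_i + ψ_t + U_iᵀV_t + log p_it,

with a negative-binomial likelihood parameterized by mean μ and dispersion
φ, Var = μ + μ²/φ (the epidemiologic convention; Poisson is the φ → ∞
limit and is available directly). Treated-cell observations Y(1) enter
neither the likelihood nor the initialization, so the fit is exactly
invariant to them — the package tests this bit-for-bit.

**Priors.** α, γ_i, ψ_t ~ Normal(0, 5²); U, V entries ~ Normal(0, 1²);
dispersion through η = 1/√φ ~ half-Normal(0, 5), which places the Poisson
model at the boundary η = 0 and lets the data pull toward overdispersion.
These are weakly informative defaults: they stabilize the unidentified
factor block while leaving predictions data-driven.

**No identifiability constraints.** The factor decomposition is left
unidentified on purpose; constraints (e.g. triangular loadings) slow mixing
and can hurt prediction. The model is treated as a black box for the
posterior predictive of Y(0): convergence is assessed with split-R̂ on the
predicted treated-cell log-means (never on raw factors), with a warning —
never a silent pass — above 1.05.

**Sampler.** No general-purpose MCMC engine with a log-link NB latent
factor model fits this package's needs off the shelf in its dependency set,
and the sampler is part of the contribution: adaptive Metropolis-within-
Gibbs with *vectorized block updates* — all county rows (γ_i, then U_i) are
proposed jointly and accepted independently per row, likewise all time
columns (ψ_t, V_t), plus scalar updates for α and log η and an exact Gibbs
recentering move along the likelihood-invariant directions
(α ↔ mean of γ, α ↔ mean of ψ). Only the μ-dependent terms of the NB
log-pmf are recomputed inside proposals, so a full 2-chain, 1000+1000-draw
fit of a 40 × 10 panel takes roughly a second. Proposal scales adapt by
Robbins–Monro during warmup (targets 0.44 for scalar/1-d updates, 0.25 for
K-dimensional rows) and are frozen afterwards. Factor updates run twice per
sweep, which measurably improves mixing of the treated-column predictions.
Defaults: K = 4 (with a PCA advisory tool that reports the smallest K
reaching a target share of variance, computed on column-centered
log-rates), 2 chains × 1000 post-warmup draws, warmup equal to draws.

**Counterfactuals and estimands.** For each retained draw m and treated
cell, one NB sample Y_it⁽ᵐ⁾(0) is taken at that draw's mean and dispersion
(Poisson sampling above φ = 10⁸). Every estimand is an exact per-draw
transformation: θ_i⁽ᵐ⁾ = Σ_{t≥T₀}(Y_it − Y_it⁽ᵐ⁾(0));
θ*_i⁽ᵐ⁾ = 100 000·θ_i⁽ᵐ⁾/p_iT; storm excess events sum θ over the storm's
counties; the storm excess rate pools denominators (100 000·Σθ/Σp — a
mean-of-county-rates option exists, pooled reads most naturally as "the
rate across all impacted counties"); TEE is the grand sum and AER the
unweighted mean of θ* over county-level exposures. Intervals are
equal-tailed 95% posterior quantiles throughout.

**Seeding.** One master seed expands through `numpy` SeedSequence spawning
into independent per-storm sampler seeds, so per-storm fits are
reproducible in isolation and identical whether run serially or in
parallel.

## Modularized predictive stage

The second stage is deliberately cut off from the first: for each causal
draw m the Bayesian linear model θ* = Xβ + ε is conditioned on
{θ*_si⁽ᵐ⁾} and exactly one β⁽ᵐ⁾ is retained. The causal draws are
read-only inputs; running or skipping the predictive stage leaves every
causal artifact bit-identical (tested). The predictive model is regarded as
associational — it need not correspond to any true data-generating
mechanism — which is precisely why it must not be allowed to inform the
causal fits.

**Conjugate exact update.** The model uses a Normal–Inverse-Gamma prior:
β | σ² ~ N(0, σ²τ²I) with τ = 10 on the standardized design, and
σ² ~ IG(0.01, 0.01). Each per-draw conditioning is then an exact
closed-form posterior, and one (β, σ²) draw per causal draw is sampled
directly — no inner MCMC, no approximation, and M = 2000 refits share a
single Cholesky factorization. Exactness and speed are why conjugacy was
chosen over a half-Normal scale prior, which would need an inner sampler
per draw.

**Design.** Continuous features are centered and scaled by training
statistics (stored in a schema and reused at prediction time). Windspeed
and year are expanded by default with restricted cubic splines — linear
tails beyond boundary knots, truncated-power basis normalized by
(t_k − t_1)² — with 4 knots at the {0.05, 0.35, 0.65, 0.95} quantiles.
Spline features need at least three distinct training values; with very few
storms, `year` collapses and the spline should be dropped (the CLI accepts
a model YAML for this). A rank-deficient design is an error, not a warning.

**Plug-in comparator.** `fit_plugin` conditions once on the θ* posterior
means and draws M samples from that single posterior. It exists only to
quantify what propagation adds: with nonzero first-stage variance, modular
intervals are systematically wider (tested over replicates), and with
degenerate first-stage draws the two coincide in distribution.

**Prediction and model selection.** θ*_new⁽ᵐ⁾ = x_newᵀβ⁽ᵐ⁾ + N(0, σ⁽ᵐ⁾²)
per retained draw. Candidate designs are ranked by K-fold cross-validated
squared error on the θ* posterior means with seeded, deterministic fold
assignment; squared-error K-fold is the package's choice of scheme.

## Synthetic-data generator

`simulate_study` draws panels *exactly from the causal model class*: α set
by a baseline rate per 100 000 per interval, γ_i ~ N(0, 0.3²),
ψ_t ~ N(0, 0.2²), a K_true = 2 factor term with U ~ N(0, 0.3²) and
V ~ N(0, 1), log-normal county denominators, and NB(μ, φ) counts. Treated
cells in the final interval receive an injected effect targeted on the
rate scale: the effect count is round(X_siᵀβ_true·p_i/100 000 + centered
Gaussian noise), clamped so Y(1) ≥ 0. Because Y(0) is realized and stored
for every treated cell, true θ, θ*, TEE, AER, and β are known exactly.

Reference conditions (the defaults): counties of ~20 000 persons, baseline
250 events/100 000 per two-week interval (mean cell counts near 50),
φ = 8, treated windspeeds 17.4 + Gamma(2, 6) m/s, wind duration above
20 m/s tracking windspeed with ±4 h independent variability (storm
translation speed varies), and a windspeed-dominated β_true of
0.8 excess events per 100 000 per m/s. These magnitudes mirror a
Medicare-scale respiratory outcome, where average excess rates in the
single to low double digits have been reported.

What the generator does **not** emulate: spatial storm tracks and
correlated exposure across storms, population displacement, multi-outcome
correlation, staggered treatment timing, and real socioeconomic covariate
structure (covariates are independent standard normals). Passing tests
therefore demonstrate correctness of the machinery and calibration within
the model class — not robustness to real-data violations of it.

## Verification scenarios and problem sizes

The test suite verifies, among others:

- exact study-period structure and brute-force agreement of all analytic-set
  filters on toy county sets;
- K = 0 equivalence: posterior cell means against an independent
  maximum-likelihood two-way NB regression (statsmodels), every cell within
  3× combined standard errors (N = 30, T = 10);
- calibration: 95% posterior-predictive intervals for held-out null Y(0)
  cells cover truth at 95 ± 3% over 525 cells (15 panels × 35 held-out
  cells);
- effect recovery and full-pipeline recovery of the windspeed slope (sign
  and 95% coverage over 20 replicate studies of 12 storms × 10 exposures).

Recovery scenarios use deliberately well-powered conditions — counties of
~100 000 persons, φ = 200, β_windspeed = 2.0 — chosen by a power analysis
of the irreducible noise floor: θ is defined against the *realized* Y(0),
so a county's excess-rate estimate carries noise of at least
100 000·√(μ + μ²/φ)/p per exposure (≈ 25/100 000 under these conditions,
≈ 50–130 at the reference conditions). Under the reference conditions a
single small study cannot pin down the slope; the worked example in the
README uses the powered conditions for that reason. Null-bias checks use a
3-standard-error bound derived from the same floor: with 50–200 cells the
Monte-Carlo noise of a bias estimate is several tenths of an event, which
bounds what any implementation could demonstrate at desk scale.

One caveat the tests quantify rather than hide: because the predictive mean
is E[exp(lp)], posterior spread in the linear predictor inflates
counterfactual means slightly (≈ 1–2% under the test conditions, more in
small, noisy panels). This retransformation effect shrinks as panels grow
and is inherited from the log link, not from the sampler.

## Known limitations

- K is user-specified; the PCA tool is advisory only, and data-driven
  selection of K is out of scope.
- A common treatment time T₀ (the final interval) is assumed; staggered
  initiation is not supported.
- The predictive stage is unweighted: exposures with noisier first-stage
  estimates count the same as precise ones.
- Convergence diagnostics cover predicted counterfactual means only; raw
  factor parameters are unidentified by design and are not monitored.
- With very small panels (≲ 25 counties) the factor block is weakly
  identified and counterfactual predictions become heavy-tailed on the
  count scale; the R̂ warning usually fires in such fits and should be
  taken seriously.
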