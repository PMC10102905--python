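"""Bayesian matrix completion for count panels: counterfactual imputation by MCMC.

The causal model treats each storm's panel as a matrix-completion problem:
treated cells (treated county, treatment interval) hold the unobserved
counterfactual count Y(0), and a low-rank latent-factor count model is fit to
every untreated cell,

    log E[Y_it(0)] = alpha + gamma_i + psi_t + U_i . V_t + log p_it,

with a negative-binomial likelihood (Var = mu + mu^2/phi) so that
overdispersed epidemiologic counts are handled natively and the Poisson model
is recovered as phi -> infinity.  The latent factors U (county loadings) and
V (time factors) absorb smooth space-time structure, including seasonal
confounding shared between treated and control counties; the factors are left
unidentified on purpose and the model is used strictly as a black box for the
posterior predictive distribution of the missing counterfactuals.

Observed treated-cell outcomes Y(1) are never read during fitting: they enter
neither the likelihood nor the initialization, so the causal fit is invariant
to them by construction.

Sampling is adaptive Metropolis-within-Gibbs with jointly proposed,
independently accepted row/column blocks (all county rows move in one
vectorized step, likewise all time columns), which keeps a full 2-chain run
on a typical storm panel in the low seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
import pandas as pd

from .panel import PanelMatrix

_POISSON_PHI = 1e8  # dispersion above this is treated as the Poisson limit


@dataclass
class MCModelSpec:
    """Configuration of the matrix-completion model and its sampler."""

    K: int = 4
    likelihood: str = "negative-binomial"
    alpha_prior_scale: float = 5.0
    county_prior_scale: float = 5.0
    time_prior_scale: float = 5.0
    factor_prior_scale: float = 1.0
    dispersion_prior_scale: float = 5.0
    chains: int = 2
    draws: int = 1000          # post-warmup draws per chain
    warmup: int | None = None  # defaults to `draws`
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.likelihood not in ("negative-binomial", "poisson"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.chains < 1 or self.draws < 1:
            raise ValueError("chains and draws must be positive")


@dataclass
class PosteriorDraws:
    """Stacked posterior draws of all model parameters, chains concatenated."""

    alpha: np.ndarray        # (M,)
    gamma: np.ndarray        # (M, N)
    psi: np.ndarray          # (M, T)
    U: np.ndarray            # (M, N, K)
    V: np.ndarray            # (M, T, K)
    phi: np.ndarray          # (M,) NB dispersion (inf for Poisson)
    n_chains: int
    draws_per_chain: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.alpha.shape[0]

    def cell_log_mean_draws(self, log_offsets: np.ndarray) -> np.ndarray:
        """Per-draw log E[Y_it(0)] for every cell; shape (M, N, T)."""
        lp = (
            self.alpha[:, None, None]
            + self.gamma[:, :, None]
            + self.psi[:, None, :]
            + np.einsum("mik,mtk->mit", self.U, self.V)
        )
        return lp + log_offsets[None, :, :]


@dataclass
class CounterfactualDraws:
    """Posterior-predictive samples of Y(0) for each treated cell."""

    y0: np.ndarray     # (M, C) non-negative integers
    cells: list        # C (county_id, interval_index) pairs, row-major
    rows: np.ndarray   # (C,) panel row of each cell
    cols: np.ndarray   # (C,) panel column of each cell

    @property
    def M(self) -> int:
        return self.y0.shape[0]


def linear_predictor(params: dict, i: int, t: int, p_it: float) -> float:
    """Log mean count for one cell under one parameter draw.

    ``params`` carries scalars/arrays ``alpha``, ``gamma``, ``psi``, ``U``,
    ``V``; indices are zero-based.
    """
    if not p_it > 0:
        raise ValueError(f"offset must be positive, got {p_it}")
    U = np.asarray(params["U"])
    V = np.asarray(params["V"])
    uv = float(U[i] @ V[t]) if U.size else 0.0
    return float(params["alpha"] + params["gamma"][i] + params["psi"][t] + uv + np.log(p_it))


def _nb_partial_ll(y, mu, phi):
    """Terms of the NB log-pmf that depend on the mean (for MH ratios)."""
    return y * np.log(mu) - (y + phi) * np.log(phi + mu)


def _pois_partial_ll(y, mu):
    return y * np.log(mu) - mu


def _nb_full_ll(y, mu, phi):
    return (
        gammaln(y + phi)
        - gammaln(phi)
        + phi * np.log(phi)
        + y * np.log(mu)
        - (y + phi) * np.log(phi + mu)
    )


class _AdaptiveScale:
    """Robbins–Monro adaptation of log proposal scales during warmup."""

    def __init__(self, shape, target, init=0.2):
        self.log_s = np.full(shape, np.log(init))
        self.target = target
        self.k = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accepted):
        self.k += 1
        rate = self.k ** -0.6
        self.log_s += rate * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_s, -10.0, 4.0, out=self.log_s)


def _run_chain(y, obs, logp, spec: MCModelSpec, rng: np.random.Generator):
    """One MCMC chain.  Returns dict of stacked post-warmup draws.

    `y` counts (N,T), `obs` boolean mask of cells in the likelihood,
    `logp` log offsets (N,T).  Treated cells (obs False) are never read.
    """
    N, T = y.shape
    K = spec.K
    nb = spec.likelihood == "negative-binomial"
    warmup = spec.warmup if spec.warmup is not None else spec.draws

    yo = np.where(obs, y, 0).astype(float)  # masked-out values zeroed, never used
    obs_f = obs.astype(float)

    # initialize from observed cells only
    with np.errstate(divide="ignore"):
        lograte = np.log((yo + 0.5) / np.exp(logp))
    n_row = obs_f.sum(axis=1)
    n_col = obs_f.sum(axis=0)
    if np.any(n_row == 0) or np.any(n_col == 0):
        raise ValueError("every county and interval needs at least one untreated cell")
    mean_all = float((lograte * obs_f).sum() / obs_f.sum())
    alpha = mean_all
    gamma = (lograte * obs_f).sum(axis=1) / n_row - mean_all
    psi = (lograte * obs_f).sum(axis=0) / n_col - mean_all
    U = 0.01 * rng.standard_normal((N, K))
    V = 0.01 * rng.standard_normal((T, K))
    log_eta = np.log(0.3)  # eta = 1/sqrt(phi); phi ~ 11 at init

    lp = alpha + gamma[:, None] + psi[None, :] + U @ V.T + logp
    mu = np.exp(lp)

    def phi_now():
        return np.inf if not nb else float(np.exp(-2.0 * log_eta))

    def partial_rowsums(mu_mat, phi):
        if nb and np.isfinite(phi):
            cell = _nb_partial_ll(yo, mu_mat, phi)
        else:
            cell = _pois_partial_ll(yo, mu_mat)
        return np.where(obs, cell, 0.0).sum(axis=1), np.where(obs, cell, 0.0).sum(axis=0)

    sa = spec.alpha_prior_scale
    sg = spec.county_prior_scale
    st = spec.time_prior_scale
    sf = spec.factor_prior_scale
    sd = spec.dispersion_prior_scale

    ad_alpha = _AdaptiveScale((), 0.44)
    ad_gamma = _AdaptiveScale(N, 0.44)
    ad_psi = _AdaptiveScale(T, 0.44)
    ad_U = _AdaptiveScale(N, 0.25 if K > 1 else 0.44)
    ad_V = _AdaptiveScale(T, 0.25 if K > 1 else 0.44)
    ad_eta = _AdaptiveScale((), 0.44)

    n_iter = warmup + spec.draws
    out = {
        "alpha": np.empty(spec.draws),
        "gamma": np.empty((spec.draws, N)),
        "psi": np.empty((spec.draws, T)),
        "U": np.empty((spec.draws, N, K)),
        "V": np.empty((spec.draws, T, K)),
        "phi": np.empty(spec.draws),
    }

    row_ll, col_ll = partial_rowsums(mu, phi_now())

    def recenter(alpha, vec, s_vec):
        # exact Gibbs move along the likelihood-invariant direction
        # alpha -> alpha + d, vec -> vec - d (lp unchanged)
        prec = 1.0 / sa**2 + vec.size / s_vec**2
        mean = (-alpha / sa**2 + vec.sum() / s_vec**2) / prec
        d = mean + rng.standard_normal() / np.sqrt(prec)
        return alpha + d, vec - d

    for it in range(n_iter):
        adapt = it < warmup
        phi = phi_now()

        # --- alpha (global intercept), scalar random walk
        da = ad_alpha.scale * rng.standard_normal()
        mu_prop = mu * np.exp(da)
        row_p, col_p = partial_rowsums(mu_prop, phi)
        logr = (row_p.sum() - row_ll.sum()) + ((alpha**2) - (alpha + da) ** 2) / (2 * sa**2)
        acc = np.log(rng.uniform()) < logr
        if acc:
            alpha += da
            mu = mu_prop
            row_ll, col_ll = row_p, col_p
        if adapt:
            ad_alpha.update(acc)

        # --- gamma rows: joint proposal, independent row acceptance
        dg = ad_gamma.scale * rng.standard_normal(N)
        mu_prop = mu * np.exp(dg[:, None])
        row_p, _ = partial_rowsums(mu_prop, phi)
        logr = (row_p - row_ll) + (gamma**2 - (gamma + dg) ** 2) / (2 * sg**2)
        acc = np.log(rng.uniform(size=N)) < logr
        gamma = np.where(acc, gamma + dg, gamma)
        mu = np.where(acc[:, None], mu_prop, mu)
        if adapt:
            ad_gamma.update(acc)
        row_ll, col_ll = partial_rowsums(mu, phi)

        # --- psi columns
        dp = ad_psi.scale * rng.standard_normal(T)
        mu_prop = mu * np.exp(dp[None, :])
        _, col_p = partial_rowsums(mu_prop, phi)
        logr = (col_p - col_ll) + (psi**2 - (psi + dp) ** 2) / (2 * st**2)
        acc = np.log(rng.uniform(size=T)) < logr
        psi = np.where(acc, psi + dp, psi)
        mu = np.where(acc[None, :], mu_prop, mu)
        if adapt:
            ad_psi.update(acc)
        row_ll, col_ll = partial_rowsums(mu, phi)

        # --- likelihood-invariant recentering of the level terms
        alpha, gamma = recenter(alpha, gamma, sg)
        alpha, psi = recenter(alpha, psi, st)

        for _ in range(2 if K > 0 else 0):
            # --- U rows (county loadings)
            dU = ad_U.scale[:, None] * rng.standard_normal((N, K))
            mu_prop = mu * np.exp(dU @ V.T)
            row_p, _ = partial_rowsums(mu_prop, phi)
            pr = ((U**2).sum(axis=1) - ((U + dU) ** 2).sum(axis=1)) / (2 * sf**2)
            logr = (row_p - row_ll) + pr
            acc = np.log(rng.uniform(size=N)) < logr
            U = np.where(acc[:, None], U + dU, U)
            mu = np.where(acc[:, None], mu_prop, mu)
            if adapt:
                ad_U.update(acc)
            row_ll, col_ll = partial_rowsums(mu, phi)

            # --- V columns (time factors)
            dV = ad_V.scale[:, None] * rng.standard_normal((T, K))
            mu_prop = mu * np.exp(U @ dV.T)
            _, col_p = partial_rowsums(mu_prop, phi)
            pr = ((V**2).sum(axis=1) - ((V + dV) ** 2).sum(axis=1)) / (2 * sf**2)
            logr = (col_p - col_ll) + pr
            acc = np.log(rng.uniform(size=T)) < logr
            V = np.where(acc[:, None], V + dV, V)
            mu = np.where(acc[None, :], mu_prop, mu)
            if adapt:
                ad_V.update(acc)
            row_ll, col_ll = partial_rowsums(mu, phi)

        if nb:
            # --- dispersion via eta = 1/sqrt(phi), half-Normal(0, sd) prior,
            #     random walk on log eta (Jacobian: + log eta)
            dl = ad_eta.scale * rng.standard_normal()
            log_eta_p = log_eta + dl
            phi_p = float(np.exp(-2.0 * log_eta_p))
            cur = np.where(obs, _nb_full_ll(yo, mu, phi), 0.0).sum()
            prop = np.where(obs, _nb_full_ll(yo, mu, phi_p), 0.0).sum()
            eta, eta_p = np.exp(log_eta), np.exp(log_eta_p)
            logprior = lambda e, le: -(e**2) / (2 * sd**2) + le
            logr = (prop - cur) + logprior(eta_p, log_eta_p) - logprior(eta, log_eta)
            acc = np.log(rng.uniform()) < logr
            if acc:
                log_eta = log_eta_p
                row_ll, col_ll = partial_rowsums(mu, phi_p)
            if adapt:
                ad_eta.update(acc)

        if it >= warmup:
            j = it - warmup
            out["alpha"][j] = alpha
            out["gamma"][j] = gamma
            out["psi"][j] = psi
            out["U"][j] = U
            out["V"][j] = V
            out["phi"][j] = phi_now()

    return out


def _split_rhat(x: np.ndarray) -> np.ndarray:
    """Split-R̂ over axis layout (chains, draws, ...)."""
    c, n = x.shape[0], x.shape[1]
    half = n // 2
    parts = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, nn = parts.shape[0], parts.shape[1]
    means = parts.mean(axis=1)
    variances = parts.var(axis=1, ddof=1)
    B = nn * means.var(axis=0, ddof=1)
    W = variances.mean(axis=0)
    var_plus = (nn - 1) / nn * W + B / nn
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(W > 0, rhat, 1.0)


class NegBinMatrixCompletion(BaseEstimator):
    """Negative-binomial matrix-completion model for causal panel counts.

    Parameters
    ----------
    K : int
        Number of latent factors (0 reduces the model to a two-way
        county+time NB regression).
    likelihood : {"negative-binomial", "poisson"}
    chains, draws, warmup : int
        MCMC layout; `draws` is post-warmup draws per chain and `warmup`
        defaults to `draws`.
    *_prior_scale : float
        SDs of the Normal priors on the intercept, county and time effects
        and factor entries; half-Normal scale on 1/sqrt(dispersion).
    random_state : int or None
        Master seed; chains receive independent spawned streams.

    Attributes
    ----------
    draws_ : PosteriorDraws
    diagnostics_ : dict with split-R̂ of treated-cell (or overall) predicted
        log-means and per-chain layout; a convergence warning is issued, not
        silenced, when R̂ exceeds 1.05.
    """

    def __init__(
        self,
        K: int = 4,
        likelihood: str = "negative-binomial",
        chains: int = 2,
        draws: int = 1000,
        warmup: int | None = None,
        alpha_prior_scale: float = 5.0,
        county_prior_scale: float = 5.0,
        time_prior_scale: float = 5.0,
        factor_prior_scale: float = 1.0,
        dispersion_prior_scale: float = 5.0,
        random_state: int | None = None,
    ):
        self.K = K
        self.likelihood = likelihood
        self.chains = chains
        self.draws = draws
        self.warmup = warmup
        self.alpha_prior_scale = alpha_prior_scale
        self.county_prior_scale = county_prior_scale
        self.time_prior_scale = time_prior_scale
        self.factor_prior_scale = factor_prior_scale
        self.dispersion_prior_scale = dispersion_prior_scale
        self.random_state = random_state

    def _spec(self) -> MCModelSpec:
        return MCModelSpec(
            K=self.K,
            likelihood=self.likelihood,
            alpha_prior_scale=self.alpha_prior_scale,
            county_prior_scale=self.county_prior_scale,
            time_prior_scale=self.time_prior_scale,
            factor_prior_scale=self.factor_prior_scale,
            dispersion_prior_scale=self.dispersion_prior_scale,
            chains=self.chains,
            draws=self.draws,
            warmup=self.warmup,
            seed=self.random_state,
        )

    def fit(self, panel: PanelMatrix, y=None) -> "NegBinMatrixCompletion":
        spec = self._spec()
        if panel.n_counties <= spec.K or panel.n_intervals <= spec.K:
            raise ValueError(
                f"K={spec.K} must be well below min(N, T)={min(panel.n_counties, panel.n_intervals)}"
            )
        obs = panel.mask == 0
        logp = np.log(panel.offsets)
        if np.all(panel.counts[obs] == 0):
            warnings.warn("all observed counts are zero; fit proceeds", stacklevel=2)

        seeds = np.random.SeedSequence(self.random_state).spawn(spec.chains)
        chain_draws = [
            _run_chain(panel.counts, obs, logp, spec, np.random.default_rng(s))
            for s in seeds
        ]
        stack = {k: np.concatenate([d[k] for d in chain_draws]) for k in chain_draws[0]}
        draws = PosteriorDraws(
            alpha=stack["alpha"],
            gamma=stack["gamma"],
            psi=stack["psi"],
            U=stack["U"],
            V=stack["V"],
            phi=stack["phi"],
            n_chains=spec.chains,
            draws_per_chain=spec.draws,
        )

        # convergence assessed on predicted log-means (treated cells if any),
        # never on the unidentifiable raw factors
        lm = draws.cell_log_mean_draws(logp)
        rows, cols = np.nonzero(panel.mask)
        if rows.size:
            track = lm[:, rows, cols]
        else:
            track = lm.mean(axis=(1, 2))[:, None]
        per_chain = track.reshape(spec.chains, spec.draws, -1)
        rhat = _split_rhat(per_chain)
        diagnostics = {
            "rhat_max": float(np.nanmax(rhat)),
            "rhat": rhat,
            "n_chains": spec.chains,
            "draws_per_chain": spec.draws,
            "converged": bool(np.nanmax(rhat) < 1.05),
        }
        if not diagnostics["converged"]:
            warnings.warn(
                f"split-R̂ of predicted counterfactual means reached "
                f"{diagnostics['rhat_max']:.3f} (> 1.05)",
                stacklevel=2,
            )
        draws.diagnostics = diagnostics
        self.draws_ = draws
        self.diagnostics_ = diagnostics
        self.panel_ = panel
        return self

    def cell_mean_draws(self, panel: PanelMatrix | None = None) -> np.ndarray:
        """Per-draw posterior E[Y_it(0)] for every cell; shape (M, N, T)."""
        panel = panel if panel is not None else self.panel_
        return np.exp(self.draws_.cell_log_mean_draws(np.log(panel.offsets)))

    def sample_counterfactuals(
        self, panel: PanelMatrix | None = None, random_state: int | None = None
    ) -> CounterfactualDraws:
        """One posterior-predictive Y(0) sample per draw for each treated cell."""
        panel = panel if panel is not None else self.panel_
        if panel.counts.shape != (self.draws_.gamma.shape[1], self.draws_.psi.shape[1]):
            raise ValueError("panel shape does not match the fitted model")
        rows, cols = np.nonzero(panel.mask)
        lm = self.draws_.cell_log_mean_draws(np.log(panel.offsets))
        mu = np.exp(lm[:, rows, cols])  # (M, C)
        phi = self.draws_.phi[:, None]
        rng = np.random.default_rng(
            self.random_state if random_state is None else random_state
        )
        y0 = np.empty_like(mu, dtype=np.int64)
        nbin = np.isfinite(phi) & (phi < _POISSON_PHI)
        nbin = np.broadcast_to(nbin, mu.shape)
        if np.any(nbin):
            phi_b = np.broadcast_to(phi, mu.shape)[nbin]
            mu_b = mu[nbin]
            y0[nbin] = rng.negative_binomial(phi_b, phi_b / (phi_b + mu_b))
        if np.any(~nbin):
            y0[~nbin] = rng.poisson(mu[~nbin])
        return CounterfactualDraws(
            y0=y0,
            cells=[(panel.county_ids[r], int(c)) for r, c in zip(rows, cols)],
            rows=rows,
            cols=cols,
        )


def fit_mc_model(panel: PanelMatrix, spec: MCModelSpec | None = None) -> NegBinMatrixCompletion:
    """Fit the matrix-completion model; thin wrapper over the estimator."""
    spec = spec or MCModelSpec()
    est = NegBinMatrixCompletion(
        K=spec.K,
        likelihood=spec.likelihood,
        chains=spec.chains,
        draws=spec.draws,
        warmup=spec.warmup,
        alpha_prior_scale=spec.alpha_prior_scale,
        county_prior_scale=spec.county_prior_scale,
        time_prior_scale=spec.time_prior_scale,
        factor_prior_scale=spec.factor_prior_scale,
        dispersion_prior_scale=spec.dispersion_prior_scale,
        random_state=spec.seed,
    )
    return est.fit(panel)


def impute_counterfactuals(
    fit: NegBinMatrixCompletion, panel: PanelMatrix | None = None, seed: int | None = None
) -> CounterfactualDraws:
    """Posterior-predictive counterfactual counts for each treated cell."""
    return fit.sample_counterfactuals(panel, random_state=seed)


def choose_K_by_pca(panels, variance_target: float = 0.7):
    """Advisory choice of the factor dimension from exploratory PCA.

    For each panel, PCA is run on the column-centered log-rate matrix
    log((Y + 0.5) / p); the suggested K is the smallest number of components
    whose mean cumulative variance explained across panels reaches the
    target.  Returns ``(K, table)`` where the table is the full scree.
    Raw ndarrays are also accepted (used as-is, no rate transform).
    """
    if not 0 < variance_target < 1:
        raise ValueError("variance_target must lie in (0, 1)")
    panels = list(panels)
    if not panels:
        raise ValueError("need at least one panel")
    curves = []
    for p in panels:
        if isinstance(p, PanelMatrix):
            X = np.log((p.counts + 0.5) / p.offsets)
        else:
            X = np.asarray(p, dtype=float)
        X = X - X.mean(axis=0, keepdims=True)
        if np.allclose(X, 0):
            raise ValueError("degenerate (constant) matrix: PCA undefined")
        n_comp = min(X.shape)
        ratios = PCA(n_components=n_comp).fit(X).explained_variance_ratio_
        curves.append(np.cumsum(ratios))
    width = max(len(c) for c in curves)
    padded = np.vstack([np.pad(c, (0, width - len(c)), constant_values=1.0) for c in curves])
    mean_cum = padded.mean(axis=0)
    meets = np.flatnonzero(mean_cum >= variance_target)
    K = int(meets[0]) + 1 if meets.size else width
    table = pd.DataFrame(
        {"K": np.arange(1, width + 1), "mean_cumulative_variance_explained": mean_cum}
    )
    return K, table
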