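"""Synthetic multi-storm panel generator with known ground truth.

Generates county x interval count panels drawn exactly from the
matrix-completion model class — log-linear low-rank baseline (global
intercept, county and interval deviations, K_true latent factors),
population offsets, negative-binomial noise — plus a treated block in the
final interval whose injected effect is targeted on the excess-rate scale:
the expected excess rate of a treated exposure equals X' beta_true for its
realized storm/county features.  Because counterfactual Y(0) draws are
retained for every treated cell, every downstream quantity (theta, theta*,
TEE, AER, beta) has an exactly known truth for recovery and calibration
testing.

Default magnitudes emulate a Medicare-scale outcome: county denominators
around 20 000 beneficiaries (log-normal), a baseline of 250 events per
100 000 per two-week interval (mean cell counts near 50), moderate
overdispersion (phi = 8), and a windspeed-dominated effect profile in which
an additional m/s of maximum sustained wind adds 0.8 excess events per
100 000 — storm-force exposures therefore produce excess rates in the single
to low double digits, the order reported for respiratory outcomes in this
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GALE_FORCE_MS, PanelMatrix

RATE_SCALE = 100_000.0


def _default_beta() -> dict:
    return {
        "intercept": -8.0,
        "max_windspeed": 0.8,
        "duration20": 0.15,
        "year": 0.0,
        "n_exposures": -0.5,
        "median_income": 0.0,
        "pct_white": 0.0,
    }


FEATURE_COLUMNS = (
    "max_windspeed",
    "duration20",
    "year",
    "n_exposures",
    "median_income",
    "pct_white",
)


@dataclass
class SimConfig:
    """Study-generating conditions (defaults are the package's reference scenario)."""

    n_storms: int = 6
    n_counties: int = 30          # per storm
    n_treated: int = 10           # per storm
    T: int = 10
    K_true: int = 2
    factor_scale: float = 0.3     # SD of U entries (V entries are unit normal)
    county_scale: float = 0.3     # SD of gamma_i
    time_scale: float = 0.2       # SD of psi_t
    baseline_rate: float = 250.0  # events per 100 000 per two-week interval
    dispersion: float = 8.0       # NB size phi; np.inf gives Poisson counts
    beta_true: dict = field(default_factory=_default_beta)
    effect_noise_rate_sd: float = 2.0  # SD of effect noise on the per-100k scale
    pop_log_mean: float = float(np.log(20_000.0))
    pop_log_sd: float = 0.5
    windspeed_gamma_shape: float = 2.0
    windspeed_gamma_scale: float = 6.0
    year_range: tuple = (1999, 2015)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treated > self.n_counties:
            raise ValueError("n_treated cannot exceed n_counties")
        for name in ("factor_scale", "county_scale", "time_scale", "baseline_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive (np.inf for Poisson)")


@dataclass
class SimTruth:
    """Ground truth for one simulated study (or one storm slice)."""

    y0_treated: np.ndarray        # realized Y(0) at treated cells, exposure order
    theta: np.ndarray             # realized Y(1) - Y(0) per exposure
    theta_star: np.ndarray        # per-100k version
    beta_true: dict
    features: pd.DataFrame        # one row per exposure (storm_id, county_id, X)
    tee: float
    aer: float


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if np.isfinite(phi) and phi < 1e8:
        return rng.negative_binomial(phi, phi / (phi + mu))
    return rng.poisson(mu)


def _storm_rng(config: SimConfig, storm_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), int(storm_index)])


def simulate_panel(config: SimConfig, storm_index: int = 0):
    """One storm's panel plus its ground-truth slice.

    Returns ``(panel, features, truth)``: the :class:`PanelMatrix` with the
    treated block in the final interval, the per-exposure feature table, and
    a :class:`SimTruth` restricted to this storm.  Deterministic in
    ``(config.seed, storm_index)``.
    """
    rng = _storm_rng(config, storm_index)
    N, T, K = config.n_counties, config.T, config.K_true
    storm_id = f"storm_{storm_index:03d}"
    county_ids = [f"{storm_id}_c{j:04d}" for j in range(N)]  # treated first

    alpha = float(np.log(config.baseline_rate / RATE_SCALE))
    gamma = config.county_scale * rng.standard_normal(N)
    psi = config.time_scale * rng.standard_normal(T)
    U = config.factor_scale * rng.standard_normal((N, K))
    V = rng.standard_normal((T, K))
    pop = rng.lognormal(config.pop_log_mean, config.pop_log_sd, size=N)
    offsets = np.tile(pop[:, None], (1, T))

    lp = alpha + gamma[:, None] + psi[None, :] + U @ V.T + np.log(offsets)
    mu0 = np.exp(lp)
    if np.any(~np.isfinite(mu0)):
        raise ValueError("configuration produced non-finite expected counts")
    y0 = _nb_sample(rng, mu0, config.dispersion)

    n_t = config.n_treated
    ws = np.empty(N)
    ws[:n_t] = GALE_FORCE_MS + rng.gamma(
        config.windspeed_gamma_shape, config.windspeed_gamma_scale, size=n_t
    )
    ws[n_t:] = rng.uniform(0.0, GALE_FORCE_MS - 0.5, size=N - n_t)
    year = int(rng.integers(config.year_range[0], config.year_range[1] + 1))
    features = pd.DataFrame(
        {
            "storm_id": storm_id,
            "county_id": county_ids[:n_t],
            "max_windspeed": ws[:n_t],
            # duration tracks peak windspeed but storm translation speed adds
            # substantial independent variability
            "duration20": np.clip(
                (ws[:n_t] - 20.0) * 0.8 + rng.normal(0.0, 4.0, size=n_t), 0.0, None
            ),
            "year": float(year),
            "n_exposures": (1 + rng.poisson(2.0, size=n_t)).astype(float),
            "median_income": rng.standard_normal(n_t),
            "pct_white": rng.standard_normal(n_t),
        }
    )

    beta = dict(config.beta_true)
    rate_effect = np.full(n_t, beta.get("intercept", 0.0))
    for f in FEATURE_COLUMNS:
        rate_effect += beta.get(f, 0.0) * features[f].to_numpy()
    count_scale = pop[:n_t] / RATE_SCALE
    effect = np.rint(
        rate_effect * count_scale
        + rng.normal(0.0, config.effect_noise_rate_sd * count_scale)
    ).astype(np.int64)

    counts = y0.copy()
    t0 = T - 1
    y0_cell = y0[:n_t, t0]
    y1_cell = np.maximum(y0_cell + effect, 0)  # events cannot go negative
    counts[:n_t, t0] = y1_cell
    mask = np.zeros((N, T), dtype=int)
    mask[:n_t, t0] = 1

    panel = PanelMatrix(
        counts=counts,
        mask=mask,
        offsets=offsets,
        county_ids=county_ids,
        interval_labels=[f"interval_{j + 1}" for j in range(T)],
        t0=t0,
    )
    theta = (y1_cell - y0_cell).astype(float)
    theta_star = RATE_SCALE * theta / pop[:n_t]
    truth = SimTruth(
        y0_treated=y0_cell.astype(np.int64),
        theta=theta,
        theta_star=theta_star,
        beta_true=beta,
        features=features,
        tee=float(theta.sum()),
        aer=float(theta_star.mean()),
    )
    return panel, features, truth


@dataclass
class SimStudy:
    """A full simulated multi-storm study."""

    panels: list
    features: pd.DataFrame
    truth: SimTruth
    config: SimConfig


def simulate_study(config: SimConfig) -> SimStudy:
    """Simulate all storms and aggregate study-wide truth."""
    panels, feats, truths = [], [], []
    for s in range(config.n_storms):
        panel, f, t = simulate_panel(config, s)
        panels.append(panel)
        feats.append(f)
        truths.append(t)
    features = pd.concat(feats, ignore_index=True)
    theta = np.concatenate([t.theta for t in truths])
    theta_star = np.concatenate([t.theta_star for t in truths])
    truth = SimTruth(
        y0_treated=np.concatenate([t.y0_treated for t in truths]),
        theta=theta,
        theta_star=theta_star,
        beta_true=dict(config.beta_true),
        features=features,
        tee=float(theta.sum()),
        aer=float(theta_star.mean()),
    )
    return SimStudy(panels=panels, features=features, truth=truth, config=config)
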