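"""Causal estimands built from counterfactual draws.

All quantities are deterministic per-draw transformations of the
posterior-predictive counterfactual samples, so their posteriors are exact
functionals of the matrix-completion posterior:

* individual excess events (IEE), theta_i = sum_{t >= T0} (Y_it - Y_it(0));
  with the single treated final interval this is Y_iT - Y_iT(0);
* individual excess rate, theta*_i = 100000 * theta_i / p_iT;
* storm-level excess events (sum of theta over the storm's treated counties)
  and excess rate (pooled, 100000 * sum theta / sum p, by default);
* study-wide total excess events (TEE, grand sum) and average excess rate
  (AER, unweighted mean of theta* over all county-level exposures).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mc import CounterfactualDraws
from .panel import PanelMatrix

RATE_SCALE = 100_000.0


@dataclass
class EffectPosterior:
    """Per-county excess-event and excess-rate draws for one storm."""

    storm_id: str
    county_ids: list          # n treated counties
    theta: np.ndarray         # (M, n) excess-event draws
    theta_star: np.ndarray    # (M, n) excess-rate draws per 100 000
    populations: np.ndarray   # (n,) treatment-interval denominators p_iT

    def __post_init__(self) -> None:
        if self.theta.shape != self.theta_star.shape:
            raise ValueError("theta and theta_star shapes differ")
        if self.theta.shape[1] != len(self.county_ids):
            raise ValueError("draw columns do not match county ids")
        expected = RATE_SCALE * self.theta / self.populations[None, :]
        if not np.allclose(self.theta_star, expected):
            raise ValueError("theta_star must equal 100000 * theta / p per draw")

    @property
    def M(self) -> int:
        return self.theta.shape[0]


def compute_iee(y_obs: np.ndarray, cf: CounterfactualDraws, county_ids=None):
    """Excess-event draws per treated county.

    ``y_obs`` holds the observed treated-cell counts aligned with
    ``cf.cells``; draws for cells of the same county (multiple treated
    intervals) are summed.  Returns ``(county_ids, theta)`` with theta of
    shape (M, n_counties).
    """
    y_obs = np.asarray(y_obs)
    if y_obs.shape != (cf.y0.shape[1],):
        raise ValueError(
            f"y_obs has shape {y_obs.shape}, expected ({cf.y0.shape[1]},) aligned to cells"
        )
    cell_theta = y_obs[None, :] - cf.y0  # (M, C)
    ids = [c for c, _ in cf.cells] if county_ids is None else list(county_ids)
    uniq = list(dict.fromkeys(ids))  # preserve first-appearance (panel row) order
    cols = {c: [] for c in uniq}
    for j, c in enumerate(ids):
        cols[c].append(j)
    theta = np.column_stack([cell_theta[:, cols[c]].sum(axis=1) for c in uniq])
    return uniq, theta


def excess_rate(theta, p) -> np.ndarray:
    """Excess events per 100 000 population."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("population must be positive")
    return RATE_SCALE * np.asarray(theta) / p


def effect_posterior_from_cf(
    panel: PanelMatrix, cf: CounterfactualDraws, storm_id: str
) -> EffectPosterior:
    """Assemble the per-county effect posterior for one storm's panel."""
    y_obs = panel.counts[cf.rows, cf.cols]
    ids = [panel.county_ids[r] for r in cf.rows]
    uniq, theta = compute_iee(y_obs, cf, county_ids=ids)
    row_of = {panel.county_ids[r]: r for r in cf.rows}
    pops = np.array([panel.offsets[row_of[c], panel.t0] for c in uniq])
    return EffectPosterior(
        storm_id=storm_id,
        county_ids=uniq,
        theta=theta,
        theta_star=excess_rate(theta, pops[None, :]),
        populations=pops,
    )


def _summary(draws: np.ndarray) -> dict:
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return {"mean": float(np.mean(draws)), "q2.5": float(lo), "q97.5": float(hi)}


def summarize_storm(effects: EffectPosterior, rate: str = "pooled") -> dict:
    """Storm-level excess events and excess rate, draws plus summaries.

    The storm excess rate pools denominators, 100000 * sum(theta) / sum(p);
    ``rate="mean"`` instead averages the county rates.
    """
    if effects.theta.shape[1] < 1:
        raise ValueError("storm has no treated counties")
    event_draws = effects.theta.sum(axis=1)
    if rate == "pooled":
        rate_draws = RATE_SCALE * event_draws / float(effects.populations.sum())
    elif rate == "mean":
        rate_draws = effects.theta_star.mean(axis=1)
    else:
        raise ValueError(f"unknown rate convention {rate!r}")
    return {
        "storm_id": effects.storm_id,
        "excess_events_draws": event_draws,
        "excess_rate_draws": rate_draws,
        "excess_events": _summary(event_draws),
        "excess_rate": _summary(rate_draws),
    }


def summarize_study(effects: list) -> dict:
    """Study-wide TEE and AER draws and summaries across all storms.

    TEE draws are the grand per-draw sum of theta over every storm and
    county; AER draws are the unweighted per-draw mean of theta* over all
    county-level exposures.  Requires a common draw count M.
    """
    if not effects:
        raise ValueError("no effect posteriors supplied")
    Ms = {e.M for e in effects}
    if len(Ms) != 1:
        raise ValueError(f"draw counts differ across storms: {sorted(Ms)}")
    theta_all = np.concatenate([e.theta for e in effects], axis=1)
    theta_star_all = np.concatenate([e.theta_star for e in effects], axis=1)
    tee = theta_all.sum(axis=1)
    aer = theta_star_all.mean(axis=1)
    return {
        "tee_draws": tee,
        "aer_draws": aer,
        "tee": _summary(tee),
        "aer": _summary(aer),
        "n_exposures": theta_all.shape[1],
        "n_storms": len(effects),
    }


def county_estimates_table(effects: list, outcome: str = "outcome") -> pd.DataFrame:
    """Tidy per-exposure posterior summaries for theta and theta*."""
    rows = []
    for e in effects:
        for j, cid in enumerate(e.county_ids):
            th, ts = _summary(e.theta[:, j]), _summary(e.theta_star[:, j])
            rows.append(
                {
                    "storm_id": e.storm_id,
                    "county_id": cid,
                    "outcome": outcome,
                    "theta_mean": th["mean"],
                    "theta_q2.5": th["q2.5"],
                    "theta_q97.5": th["q97.5"],
                    "theta_star_mean": ts["mean"],
                    "theta_star_q2.5": ts["q2.5"],
                    "theta_star_q97.5": ts["q97.5"],
                    "population": float(e.populations[j]),
                }
            )
    return pd.DataFrame(rows)
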