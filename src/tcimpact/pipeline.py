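"""Orchestration: per-storm causal fits -> estimands -> modular predictive fit.

Per-storm causal models share no parameters, so they are embarrassingly
parallel and each receives its own deterministically derived seed; serial and
parallel execution produce identical output.  The predictive stage consumes
the causal draws read-only (cut posterior), so running or skipping it leaves
every causal artifact bit-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tcio
from .estimands import (
    EffectPosterior,
    county_estimates_table,
    effect_posterior_from_cf,
    summarize_study,
)
from .mc import MCModelSpec, NegBinMatrixCompletion, fit_mc_model, impute_counterfactuals
from .modular import BayesianModularRegression, PredictiveModelSpec, fit_modular, fit_plugin
from .panel import PanelMatrix


def derive_storm_seeds(master_seed: int | None, n_storms: int) -> list:
    """Expand one master seed into independent per-storm sampler seeds."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n_storms)]


def fit_storm(
    panel: PanelMatrix, storm_id: str, mc_spec: MCModelSpec, seed: int
) -> EffectPosterior:
    """Causal fit and effect posterior for one storm."""
    spec = MCModelSpec(**{**mc_spec.__dict__, "seed": seed})
    fit = fit_mc_model(panel, spec)
    cf = impute_counterfactuals(fit, panel, seed=seed + 1)
    return effect_posterior_from_cf(panel, cf, storm_id)


def assemble_theta_star_draws(effects: list, features: pd.DataFrame) -> np.ndarray:
    """(M, n_exposures) theta* draw matrix with columns aligned to feature rows.

    Draw index m is matched across storms by position, as the modular scheme
    requires; draw counts must agree."""
    Ms = {e.M for e in effects}
    if len(Ms) != 1:
        raise ValueError(f"draw counts differ across storms: {sorted(Ms)}")
    index = {}
    for e in effects:
        for j, cid in enumerate(e.county_ids):
            index[(e.storm_id, cid)] = e.theta_star[:, j]
    cols = []
    for _, row in features.iterrows():
        key = (row["storm_id"], row["county_id"])
        if key not in index:
            raise ValueError(f"no causal draws for exposure {key}")
        cols.append(index[key])
    return np.column_stack(cols)


def analyze_study(
    panels: list,
    storm_ids: list,
    features: pd.DataFrame,
    mc_spec: MCModelSpec | None = None,
    pred_spec: PredictiveModelSpec | None = None,
    seed: int | None = 0,
    fit_predictive: bool = True,
) -> dict:
    """Full per-outcome analysis on in-memory panels.

    Returns effects, study-level summaries and (optionally) the modular and
    plug-in predictive fits."""
    mc_spec = mc_spec or MCModelSpec()
    pred_spec = pred_spec or PredictiveModelSpec()
    seeds = derive_storm_seeds(seed, len(panels))
    effects = [
        fit_storm(p, sid, mc_spec, s) for p, sid, s in zip(panels, storm_ids, seeds)
    ]
    study = summarize_study(effects)
    out = {
        "effects": effects,
        "study": study,
        "county_table": county_estimates_table(effects),
    }
    if fit_predictive and len(features):
        draws = assemble_theta_star_draws(effects, features)
        X = features.drop(columns=["storm_id", "county_id"])
        out["modular"] = fit_modular(draws, X, pred_spec, seed=seed)
        out["plugin"] = fit_plugin(draws.mean(axis=0), X, pred_spec, draws=draws.shape[0], seed=seed)
        out["theta_star_draws"] = draws
    return out


def run_pipeline(config: dict, out_dir) -> Path:
    """File-based run: read panels and features, fit, write artifacts + manifest.

    ``config`` keys: ``panel_dir``, ``storm_ids``, ``features`` (CSV path,
    optional), ``outcome``, ``mc`` / ``predictive`` (spec overrides),
    ``seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel_dir = Path(config["panel_dir"])
    storm_ids = list(config["storm_ids"])
    panels = [tcio.read_panel(panel_dir, sid) for sid in storm_ids]
    features = (
        pd.read_csv(config["features"], dtype={"county_id": str, "storm_id": str})
        if config.get("features")
        else pd.DataFrame()
    )
    mc_spec = MCModelSpec(**config.get("mc", {}))
    pred_spec = PredictiveModelSpec(**config.get("predictive", {}))
    seed = config.get("seed", 0)

    result = analyze_study(
        panels,
        storm_ids,
        features,
        mc_spec=mc_spec,
        pred_spec=pred_spec,
        seed=seed,
        fit_predictive=bool(len(features)),
    )
    result["county_table"].to_csv(out_dir / "county_estimates.csv", index=False)
    study = result["study"]
    (out_dir / "study_summary.json").write_text(
        json.dumps(
            {
                "outcome": config.get("outcome", "outcome"),
                "tee": study["tee"],
                "aer": study["aer"],
                "n_storms": study["n_storms"],
                "n_exposures": study["n_exposures"],
            },
            indent=1,
        )
    )
    if "modular" in result:
        result["modular"].coefficient_summary().to_csv(
            out_dir / "predictive_coefficients.csv", index=False
        )
    manifest = {
        "seed": seed,
        "storm_ids": storm_ids,
        "storm_seeds": derive_storm_seeds(seed, len(panels)),
        "mc": mc_spec.__dict__,
        "predictive": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in pred_spec.__dict__.items()
        },
        "inputs": {
            sid: tcio.sha256_file(panel_dir / f"{sid}_panel.csv") for sid in storm_ids
        },
    }
    tcio.write_manifest(out_dir, manifest)
    return out_dir
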