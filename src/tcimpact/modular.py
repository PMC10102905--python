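"""Modularized predictive stage: excess rates regressed on storm/county features.

The second stage relates the county-level excess rates theta*_si to a feature
vector X_si (maximum sustained windspeed, duration of winds above 20 m/s,
year, exposure count, socioeconomic covariates) through a Bayesian linear
model with restricted cubic splines on selected features (windspeed and year
by default).

Uncertainty propagates one way only ("cut" posterior): for each causal draw
m, the linear model is conditioned on the m-th draw of every exposure's
theta* and exactly one coefficient draw beta^(m) is retained, yielding M
modular draws that carry first-stage uncertainty.  Nothing is ever written
back to the causal stage.  A plug-in variant (fit once to the posterior
means) is provided solely to quantify what that propagation adds.

The linear-Gaussian model uses a Normal-Inverse-Gamma prior, so each per-draw
conditioning is an exact closed-form posterior update; with the design fixed
across draws the M refits share one Cholesky factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

DEFAULT_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (natural spline, linear beyond the
    boundary knots), in the standard truncated-power form.

    For knots t_1 < ... < t_k the k-1 columns are x itself and, for
    j = 1..k-2,

        [(x-t_j)_+^3 - (x-t_{k-1})_+^3 (t_k-t_j)/(t_k-t_{k-1})
                     + (x-t_k)_+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which keeps the columns on roughly the scale of x.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(np.unique(knots)) < 3:
        raise ValueError("need at least 3 distinct knots")
    k = len(knots)
    tk, tk1, t1 = knots[-1], knots[-2], knots[0]
    norm = (tk - t1) ** 2
    cols = [x]
    pos3 = lambda v: np.clip(v, 0.0, None) ** 3
    for j in range(k - 2):
        tj = knots[j]
        col = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / norm
        cols.append(col)
    return np.column_stack(cols)


def default_knots(x, quantiles=DEFAULT_KNOT_QUANTILES) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct values to place spline knots")
    knots = np.quantile(x, quantiles)
    if len(np.unique(knots)) < 3:  # heavy ties: fall back to unique-value spread
        knots = np.quantile(np.unique(x), quantiles)
    return knots


@dataclass
class PredictiveModelSpec:
    """Formula-lite description of the predictive design.

    ``features`` fixes the schema order; features named in
    ``spline_features`` are expanded with a restricted cubic spline at the
    given quantile knots, all others enter linearly.
    """

    features: tuple | None = None  # None: every column of X; (): intercept-only
    spline_features: tuple = ("max_windspeed", "year")
    knot_quantiles: tuple = DEFAULT_KNOT_QUANTILES
    coef_prior_scale: float = 10.0
    a0: float = 0.01
    b0: float = 0.01
    name: str = "rcs(windspeed, year) + linear"

    def resolved_features(self, X: pd.DataFrame) -> tuple:
        return tuple(X.columns) if self.features is None else tuple(self.features)


@dataclass
class _DesignSchema:
    """Frozen training-time design recipe reused at prediction time."""

    features: tuple
    spline_features: tuple
    knots: dict
    centers: np.ndarray
    scales: np.ndarray
    column_names: tuple


@dataclass
class ModularPosterior:
    """M retained coefficient/scale draws, one per causal draw."""

    beta: np.ndarray       # (M, p)
    sigma: np.ndarray      # (M,) residual SDs
    schema: _DesignSchema
    method: str = "modular"

    @property
    def M(self) -> int:
        return self.beta.shape[0]


@dataclass
class RiskPrediction:
    """Posterior-predictive excess-rate draws for one new exposure."""

    draws: np.ndarray
    mean: float
    q2_5: float
    q97_5: float
    x_new: dict = field(default_factory=dict)


def _build_design(X: pd.DataFrame, spec: PredictiveModelSpec, schema: _DesignSchema | None):
    """Raw (unstandardized) design matrix and, on first build, the schema."""
    feats = schema.features if schema is not None else spec.resolved_features(X)
    missing = [f for f in feats if f not in X.columns]
    if missing:
        raise ValueError(f"features missing from table: {missing}")
    if X[list(feats)].isna().any().any():
        raise ValueError("feature table contains missing values")
    cols, names = [], []
    knots = dict(schema.knots) if schema is not None else {}
    spline_feats = schema.spline_features if schema is not None else tuple(
        f for f in spec.spline_features if f in feats
    )
    for f in feats:
        x = X[f].to_numpy(dtype=float)
        if f in spline_feats:
            if f not in knots:
                knots[f] = default_knots(x, spec.knot_quantiles)
            B = rcs_basis(x, knots[f])
            cols.append(B)
            names.extend([f] + [f"rcs({f}){j}" for j in range(1, B.shape[1])])
        else:
            cols.append(x[:, None])
            names.append(f)
    M = np.hstack(cols) if cols else np.empty((len(X), 0))
    return M, tuple(names), knots, feats, spline_feats


def _design_from_schema(X: pd.DataFrame, spec: PredictiveModelSpec, schema: _DesignSchema):
    raw, names, _, _, _ = _build_design(X, spec, schema)
    Z = (raw - schema.centers) / schema.scales
    return np.column_stack([np.ones(len(Z)), Z])


class BayesianModularRegression(BaseEstimator, RegressorMixin):
    """Bayesian linear model fit per causal posterior draw (cut posterior).

    Parameters
    ----------
    spline_features : tuple of str
        Features expanded with restricted cubic splines (training-quantile
        knots); all other columns of X enter linearly.
    knot_quantiles : tuple
    coef_prior_scale : float
        Prior SD multiplier tau in beta | sigma^2 ~ N(0, sigma^2 tau^2 I)
        on the standardized design (intercept included).
    a0, b0 : float
        Inverse-Gamma shape/scale of the sigma^2 prior.
    method : {"modular", "plugin"}
        Modular: one exact posterior draw per causal draw of theta*.
        Plugin: n_draws draws from the single posterior conditioned on the
        theta* posterior means (the no-propagation comparator).
    n_draws : int
        Draw count for the plug-in method (ignored for modular, where M is
        inherited from the first stage).
    random_state : int or None

    Attributes
    ----------
    posterior_ : ModularPosterior
    coef_draws_, sigma_draws_ : convenience views of the retained draws.
    feature_names_ : design column names (after the intercept).
    """

    def __init__(
        self,
        features: tuple | None = None,
        spline_features: tuple = ("max_windspeed", "year"),
        knot_quantiles: tuple = DEFAULT_KNOT_QUANTILES,
        coef_prior_scale: float = 10.0,
        a0: float = 0.01,
        b0: float = 0.01,
        method: str = "modular",
        n_draws: int = 2000,
        random_state: int | None = None,
    ):
        self.features = features
        self.spline_features = spline_features
        self.knot_quantiles = knot_quantiles
        self.coef_prior_scale = coef_prior_scale
        self.a0 = a0
        self.b0 = b0
        self.method = method
        self.n_draws = n_draws
        self.random_state = random_state

    def _spec(self) -> PredictiveModelSpec:
        return PredictiveModelSpec(
            features=None if self.features is None else tuple(self.features),
            spline_features=tuple(self.spline_features),
            knot_quantiles=tuple(self.knot_quantiles),
            coef_prior_scale=self.coef_prior_scale,
            a0=self.a0,
            b0=self.b0,
        )

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "BayesianModularRegression":
        """Fit to causal draws (modular, y of shape (M, n)) or to posterior
        means (plugin, y of shape (n,))."""
        if self.method not in ("modular", "plugin"):
            raise ValueError(f"unknown method {self.method!r}")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        spec = self._spec()
        raw, names, knots, feats, spline_feats = _build_design(X, spec, None)
        centers = raw.mean(axis=0)
        scales = raw.std(axis=0, ddof=0)
        if np.any(scales == 0):
            bad = [names[j] for j in np.flatnonzero(scales == 0)]
            raise ValueError(f"constant design columns: {bad}")
        schema = _DesignSchema(
            features=feats,
            spline_features=spline_feats,
            knots=knots,
            centers=centers,
            scales=scales,
            column_names=names,
        )
        Z = np.column_stack([np.ones(len(raw)), (raw - centers) / scales])
        n, p = Z.shape
        if np.linalg.matrix_rank(Z) < p:
            raise ValueError("design matrix is rank deficient on the training exposures")

        if self.method == "modular":
            if y.ndim != 2:
                raise ValueError("modular fit expects theta* draws of shape (M, n_exposures)")
            if y.shape[1] != n:
                raise ValueError(
                    f"{y.shape[1]} draw columns do not align with {n} feature rows"
                )
            Y = y
        else:
            if y.ndim != 1 or y.shape[0] != n:
                raise ValueError("plugin fit expects one theta* mean per exposure")
            Y = np.tile(y, (int(self.n_draws), 1))
        # y columns are read-only inputs: the causal stage is never modified
        Y = Y.copy()

        tau2 = float(self.coef_prior_scale) ** 2
        Lam = Z.T @ Z + np.eye(p) / tau2
        L = np.linalg.cholesky(Lam)
        # posterior means for all draws at once: Lam^{-1} Z^T y_m
        XtY = Z.T @ Y.T                                  # (p, M)
        Mn = np.linalg.solve(L.T, np.linalg.solve(L, XtY))  # (p, M)
        an = self.a0 + n / 2.0
        quad = np.einsum("mi,mi->m", Y, Y) - np.einsum("pm,pm->m", XtY, Mn)
        bn = self.b0 + 0.5 * quad
        bn = np.maximum(bn, 1e-300)

        rng = np.random.default_rng(self.random_state)
        Mdraws = Y.shape[0]
        sigma2 = bn / rng.gamma(an, 1.0, size=Mdraws)
        zs = rng.standard_normal((Mdraws, p))
        # beta = Mn + sigma * L^{-T} z  (exact NIG draw)
        beta = Mn.T + np.sqrt(sigma2)[:, None] * np.linalg.solve(L.T, zs.T).T

        self.posterior_ = ModularPosterior(
            beta=beta, sigma=np.sqrt(sigma2), schema=schema, method=self.method
        )
        self.coef_draws_ = beta
        self.sigma_draws_ = np.sqrt(sigma2)
        self.feature_names_ = names
        return self

    def predict(self, X_new: pd.DataFrame, return_draws: bool = False):
        """Posterior-predictive excess rates for new feature vectors.

        Returns the posterior-predictive mean per row, or with
        ``return_draws=True`` a list of :class:`RiskPrediction` carrying the
        full draw vectors (linear predictor plus residual noise, one draw
        per retained beta)."""
        X_new = pd.DataFrame(X_new)
        post = self.posterior_
        Z = _design_from_schema(X_new, self._spec(), post.schema)
        lin = Z @ post.beta.T  # (n_new, M)
        rng = np.random.default_rng(self.random_state)
        noise = rng.standard_normal(lin.shape) * post.sigma[None, :]
        draws = lin + noise
        if not return_draws:
            return draws.mean(axis=1)
        out = []
        for r in range(draws.shape[0]):
            lo, hi = np.quantile(draws[r], [0.025, 0.975])
            out.append(
                RiskPrediction(
                    draws=draws[r],
                    mean=float(draws[r].mean()),
                    q2_5=float(lo),
                    q97_5=float(hi),
                    x_new=X_new.iloc[r].to_dict(),
                )
            )
        return out

    def linear_coefficient_draws(self, feature: str) -> np.ndarray:
        """Original-scale slope draws for a feature that entered linearly."""
        post = self.posterior_
        if feature in post.schema.spline_features:
            raise ValueError(f"{feature!r} is spline-expanded; no single slope exists")
        j = post.schema.column_names.index(feature)
        return post.beta[:, j + 1] / post.schema.scales[j]

    def coefficient_summary(self) -> pd.DataFrame:
        """Posterior mean and central 95% interval per design column."""
        names = ("intercept",) + tuple(self.feature_names_)
        b = self.coef_draws_
        lo, hi = np.quantile(b, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {"term": names, "mean": b.mean(axis=0), "q2.5": lo, "q97.5": hi}
        )


def fit_modular(
    theta_star_draws: np.ndarray,
    X: pd.DataFrame,
    spec: PredictiveModelSpec | None = None,
    seed: int | None = None,
) -> BayesianModularRegression:
    """Cut-posterior fit: one exact beta draw per causal theta* draw."""
    spec = spec or PredictiveModelSpec()
    est = BayesianModularRegression(
        features=spec.features,
        spline_features=spec.spline_features,
        knot_quantiles=spec.knot_quantiles,
        coef_prior_scale=spec.coef_prior_scale,
        a0=spec.a0,
        b0=spec.b0,
        method="modular",
        random_state=seed,
    )
    return est.fit(X, theta_star_draws)


def fit_plugin(
    theta_star_means: np.ndarray,
    X: pd.DataFrame,
    spec: PredictiveModelSpec | None = None,
    draws: int = 2000,
    seed: int | None = None,
) -> BayesianModularRegression:
    """No-propagation comparator: fit once to first-stage posterior means."""
    spec = spec or PredictiveModelSpec()
    est = BayesianModularRegression(
        features=spec.features,
        spline_features=spec.spline_features,
        knot_quantiles=spec.knot_quantiles,
        coef_prior_scale=spec.coef_prior_scale,
        a0=spec.a0,
        b0=spec.b0,
        method="plugin",
        n_draws=draws,
        random_state=seed,
    )
    return est.fit(X, theta_star_means)


def predict_new(model: BayesianModularRegression, X_new: pd.DataFrame):
    """Risk predictions (draws + summaries) for new exposures."""
    return model.predict(X_new, return_draws=True)


def save_modular_fit(model: BayesianModularRegression, out_dir) -> None:
    """Persist a fitted predictive model as CSV draws + JSON schema."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    post = model.posterior_
    cols = ("intercept",) + tuple(post.schema.column_names)
    pd.DataFrame(post.beta, columns=cols).to_csv(out_dir / "beta_draws.csv", index=False)
    pd.DataFrame({"sigma": post.sigma}).to_csv(out_dir / "sigma_draws.csv", index=False)
    schema = {
        "features": list(post.schema.features),
        "spline_features": list(post.schema.spline_features),
        "knots": {k: list(v) for k, v in post.schema.knots.items()},
        "centers": list(post.schema.centers),
        "scales": list(post.schema.scales),
        "column_names": list(post.schema.column_names),
        "method": post.method,
        "params": model.get_params(),
    }
    (out_dir / "schema.json").write_text(json.dumps(schema, indent=1, default=list))


def load_modular_fit(in_dir) -> BayesianModularRegression:
    """Reload a fit written by :func:`save_modular_fit`."""
    import json
    from pathlib import Path

    in_dir = Path(in_dir)
    schema_d = json.loads((in_dir / "schema.json").read_text())
    beta = pd.read_csv(in_dir / "beta_draws.csv").to_numpy()
    sigma = pd.read_csv(in_dir / "sigma_draws.csv")["sigma"].to_numpy()
    params = schema_d.pop("params")
    params["spline_features"] = tuple(params["spline_features"])
    params["knot_quantiles"] = tuple(params["knot_quantiles"])
    model = BayesianModularRegression(**params)
    schema = _DesignSchema(
        features=tuple(schema_d["features"]),
        spline_features=tuple(schema_d["spline_features"]),
        knots={k: np.asarray(v) for k, v in schema_d["knots"].items()},
        centers=np.asarray(schema_d["centers"]),
        scales=np.asarray(schema_d["scales"]),
        column_names=tuple(schema_d["column_names"]),
    )
    model.posterior_ = ModularPosterior(
        beta=beta, sigma=sigma, schema=schema, method=schema_d["method"]
    )
    model.coef_draws_ = beta
    model.sigma_draws_ = sigma
    model.feature_names_ = schema.column_names
    return model


def crossvalidate_model_menu(
    candidates: list,
    theta_star_means: np.ndarray,
    X: pd.DataFrame,
    folds: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank candidate predictive designs by K-fold held-out squared error.

    Each candidate is a :class:`PredictiveModelSpec`; per fold the model is
    conditioned on the training exposures' theta* means and the posterior
    mean of beta predicts the held-out ones.  Fold assignment is a seeded
    permutation, so the table is deterministic.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    y = np.asarray(theta_star_means, dtype=float)
    X = pd.DataFrame(X).reset_index(drop=True)
    n = len(X)
    if folds < 2 or folds > n:
        raise ValueError(f"folds must lie in [2, {n}]")
    order = np.random.default_rng(seed).permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.arange(n) % folds

    rows = []
    for idx, spec in enumerate(candidates):
        fold_mse = []
        for f in range(folds):
            train, test = assignment != f, assignment == f
            est = BayesianModularRegression(
                features=spec.features,
                spline_features=spec.spline_features,
                knot_quantiles=spec.knot_quantiles,
                coef_prior_scale=spec.coef_prior_scale,
                a0=spec.a0,
                b0=spec.b0,
                method="plugin",
                n_draws=1,
                random_state=0,
            )
            est.fit(X.loc[train], y[train])
            post = est.posterior_
            Z = _design_from_schema(X.loc[test], spec, post.schema)
            tau2 = spec.coef_prior_scale**2
            Ztr = np.column_stack(
                [
                    np.ones(int(train.sum())),
                    (_build_design(X.loc[train], spec, post.schema)[0] - post.schema.centers)
                    / post.schema.scales,
                ]
            )
            Lam = Ztr.T @ Ztr + np.eye(Ztr.shape[1]) / tau2
            beta_mean = np.linalg.solve(Lam, Ztr.T @ y[train])
            pred = Z @ beta_mean
            fold_mse.append(float(np.mean((y[test] - pred) ** 2)))
        rows.append(
            {
                "candidate": idx,
                "name": spec.name,
                "mean_mse": float(np.mean(fold_mse)),
                "sd_mse": float(np.std(fold_mse, ddof=1)) if folds > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows).sort_values("mean_mse", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
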