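import numpy as np
import pytest

from tcimpact.mc import (
    MCModelSpec,
    NegBinMatrixCompletion,
    choose_K_by_pca,
    impute_counterfactuals,
    linear_predictor,
)
from tcimpact.panel import PanelMatrix
from tcimpact.simulate import SimConfig, simulate_panel


def _params(N=5, T=10, K=2, **overrides):
    p = {
        "alpha": 0.0,
        "gamma": np.zeros(N),
        "psi": np.zeros(T),
        "U": np.zeros((N, K)),
        "V": np.zeros((T, K)),
    }
    p.update(overrides)
    return p


class TestLinearPredictor:
    def test_zero_params_unit_offset(self):
        assert linear_predictor(_params(), 0, 0, 1.0) == 0.0

    def test_intercept_only(self):
        assert linear_predictor(_params(alpha=np.log(2)), 1, 2, 1.0) == pytest.approx(np.log(2))

    def test_offset_linearity(self):
        p = _params(alpha=0.3, gamma=np.arange(5.0), U=np.ones((5, 2)), V=np.ones((10, 2)))
        base = linear_predictor(p, 2, 3, 1000.0)
        assert linear_predictor(p, 2, 3, 2000.0) == pytest.approx(base + np.log(2))

    def test_rejects_nonpositive_offset(self):
        with pytest.raises(ValueError):
            linear_predictor(_params(), 0, 0, 0.0)


class TestFit:
    def test_masking_invariance_is_exact(self, null_panel):
        """Perturbing treated-cell observations must not move the fit at all:
        Y(1) enters neither the likelihood nor the initialization."""
        panel, _, _ = null_panel
        perturbed = PanelMatrix(
            counts=np.where(panel.mask == 1, panel.counts + 137, panel.counts),
            mask=panel.mask,
            offsets=panel.offsets,
            county_ids=panel.county_ids,
            interval_labels=panel.interval_labels,
            t0=panel.t0,
        )
        kw = dict(K=2, chains=2, draws=120, warmup=120, random_state=3)
        a = NegBinMatrixCompletion(**kw).fit(panel)
        b = NegBinMatrixCompletion(**kw).fit(perturbed)
        np.testing.assert_array_equal(a.draws_.alpha, b.draws_.alpha)
        np.testing.assert_array_equal(a.draws_.gamma, b.draws_.gamma)
        np.testing.assert_array_equal(a.draws_.U, b.draws_.U)
        np.testing.assert_array_equal(a.draws_.phi, b.draws_.phi)

    def test_offset_rescaling_leaves_count_predictions_invariant(self, null_panel):
        """Multiplying every offset by c shifts alpha by -log c in the mean
        structure and leaves predicted counts unchanged within MCMC error
        (rate predictions absorb the offset)."""
        panel, _, _ = null_panel
        c = 7.0
        scaled = PanelMatrix(
            counts=panel.counts,
            mask=panel.mask,
            offsets=panel.offsets * c,
            county_ids=panel.county_ids,
            interval_labels=panel.interval_labels,
            t0=panel.t0,
        )
        kw = dict(K=2, chains=2, draws=500, warmup=500, random_state=5)
        a = NegBinMatrixCompletion(**kw).fit(panel)
        b = NegBinMatrixCompletion(**kw).fit(scaled)
        ma, mb = a.cell_mean_draws().mean(axis=0), b.cell_mean_draws().mean(axis=0)
        assert np.median(np.abs(mb - ma) / ma) < 0.05
        # the -log c shift lands on the (unidentified) level terms jointly
        level = lambda d: d.alpha + d.gamma.mean(axis=1) + d.psi.mean(axis=1)
        assert abs((level(b.draws_) - level(a.draws_)).mean() + np.log(c)) < 0.3

    def test_draw_layout_and_single_treated_cell(self):
        cfg = SimConfig(n_storms=1, n_counties=20, n_treated=1, seed=13)
        panel, _, _ = simulate_panel(cfg, 0)
        est = NegBinMatrixCompletion(K=1, chains=2, draws=80, warmup=80, random_state=0).fit(panel)
        assert est.draws_.M == 160
        cf = est.sample_counterfactuals(random_state=1)
        assert cf.y0.shape == (160, 1)

    def test_rejects_k_too_large(self, null_panel):
        panel, _, _ = null_panel
        with pytest.raises(ValueError):
            NegBinMatrixCompletion(K=10, draws=10, warmup=10).fit(panel)

    def test_two_way_fit_matches_nb_glm_oracle(self):
        """With K=0 the model is a county+time NB regression; posterior cell
        means must agree with an independent maximum-likelihood fit."""
        sm_api = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.discrete_model import NegativeBinomial

        cfg = SimConfig(
            n_storms=1,
            n_counties=30,
            n_treated=0,
            factor_scale=0.0,
            dispersion=10.0,
            seed=17,
        )
        panel, _, _ = simulate_panel(cfg, 0)
        est = NegBinMatrixCompletion(
            K=0, chains=2, draws=600, warmup=600, random_state=2
        ).fit(panel)
        mu_draws = est.cell_mean_draws()
        post_mean = mu_draws.mean(axis=0)
        post_sd = mu_draws.std(axis=0)

        N, T = panel.counts.shape
        y = panel.counts.ravel()
        county = np.repeat(np.arange(N), T)
        time = np.tile(np.arange(T), N)
        X = np.column_stack(
            [
                np.ones(y.size),
                (county[:, None] == np.arange(1, N)).astype(float),
                (time[:, None] == np.arange(1, T)).astype(float),
            ]
        )
        glm = NegativeBinomial(y, X, exposure=panel.offsets.ravel()).fit(disp=0, maxiter=200)
        k = X.shape[1]
        lp = X @ glm.params[:k] + np.log(panel.offsets.ravel())
        mu_glm = np.exp(lp)
        cov = glm.cov_params()[:k, :k]
        se_lp = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
        se_mu = mu_glm * se_lp

        combined = 3.0 * np.sqrt(se_mu**2 + post_sd.ravel() ** 2)
        frac_within = np.mean(np.abs(post_mean.ravel() - mu_glm) <= combined)
        assert frac_within >= 0.99


class TestCounterfactuals:
    def test_draws_are_nonnegative_integers(self, short_fit):
        cf = short_fit.sample_counterfactuals(random_state=11)
        assert cf.y0.dtype.kind == "i"
        assert (cf.y0 >= 0).all()
        assert cf.M == short_fit.draws_.M

    def test_mean_matches_posterior_mean_of_nb_means(self, short_fit, null_panel):
        """Law of total expectation: averaging the Y(0) draws recovers the
        posterior mean of the cell means within Monte Carlo error."""
        panel, _, _ = null_panel
        rows, cols = np.nonzero(panel.mask)
        mu = short_fit.cell_mean_draws()[:, rows, cols]
        stack = [short_fit.sample_counterfactuals(random_state=s).y0 for s in range(4)]
        y0 = np.concatenate(stack)  # ~2400 draws per cell
        target = mu.mean(axis=0)
        mc_se = np.sqrt((mu.var(axis=0) + mu.mean(axis=0) + mu.mean(axis=0) ** 2 / 5) / y0.shape[0])
        assert np.all(np.abs(y0.mean(axis=0) - target) < 5 * mc_se + 0.5)

    def test_degenerate_tiny_mean_gives_zeros(self):
        counts = np.zeros((6, 10), dtype=int)
        mask = np.zeros((6, 10), dtype=int)
        mask[0, 9] = 1
        panel = PanelMatrix(
            counts, mask, np.full((6, 10), 1e-4), [f"c{i}" for i in range(6)], list(range(10)), 9
        )
        with pytest.warns(UserWarning, match="zero"):
            est = NegBinMatrixCompletion(
                K=0, likelihood="poisson", chains=1, draws=50, warmup=50, random_state=0
            ).fit(panel)
        cf = est.sample_counterfactuals(random_state=0)
        assert (cf.y0 == 0).all()

    def test_reproducible_given_seed(self, short_fit):
        a = impute_counterfactuals(short_fit, seed=99)
        b = impute_counterfactuals(short_fit, seed=99)
        np.testing.assert_array_equal(a.y0, b.y0)


class TestChooseK:
    def test_exact_rank_two_matrix(self):
        rng = np.random.default_rng(0)
        X = np.outer(rng.normal(size=40), rng.normal(size=10)) + np.outer(
            rng.normal(size=40), rng.normal(size=10)
        )
        K, table = choose_K_by_pca([X], variance_target=0.95)
        assert K == 2
        assert table["mean_cumulative_variance_explained"].iloc[1] > 0.999

    def test_noise_matrix_needs_many_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 40))
        K, table = choose_K_by_pca([X], variance_target=0.9)
        # i.i.d. noise spreads variance over all components
        assert K >= 15
        cum = table["mean_cumulative_variance_explained"].to_numpy()
        assert np.all(np.diff(cum) > -1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            choose_K_by_pca([np.ones((8, 8))])

    def test_panel_input(self, null_panel):
        panel, _, _ = null_panel
        K, table = choose_K_by_pca([panel], variance_target=0.7)
        assert 1 <= K <= min(panel.counts.shape)
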