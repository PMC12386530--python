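import numpy as np
import pytest

import noisesleep as ns
from noisesleep.curve import FitError, InsufficientDataError, logistic_pct, weighted_r2

from conftest import grid_search_fit


def exact_bins(a, b, centers=(38, 48, 58, 68), n=500):
    """Pooled classes lying exactly on a known curve (zero-residual case)."""
    nl = np.array(centers, float)
    p = 1 / (1 + np.exp(a - b * nl))
    return nl, p, np.full_like(nl, n)


class TestFitting:
    def test_zero_residual_recovery(self):
        nl, p, w = exact_bins(5.0, 0.06)
        res = ns.ExposureResponseModel(nl, p, w).fit()
        assert res.intercept_a == pytest.approx(5.0, abs=1e-8)
        assert res.slope_b == pytest.approx(0.06, abs=1e-10)
        assert res.rsquared_weighted == pytest.approx(1.0, abs=1e-12)

    def test_glm_zero_residual_recovery(self):
        # with expectations as integer counts the GLM sees the exact curve
        nl = np.array([40.0, 50.0, 60.0, 70.0])
        p = 1 / (1 + np.exp(5.0 - 0.1 * nl))
        w = np.full(4, 10_000.0)
        # make successes integers exactly
        succ = np.round(p * w)
        res = ns.ExposureResponseModel(nl, succ / w, w).fit(method="binomial_glm")
        assert res.intercept_a == pytest.approx(5.0, abs=1e-3)
        assert res.slope_b == pytest.approx(0.1, abs=1e-4)

    def test_agrees_with_grid_search_oracle(self, pooled_ref):
        model = ns.ExposureResponseModel.from_pooled(pooled_ref, "HR")
        res = model.fit()
        a_star, b_star = grid_search_fit(
            model.nl, model.proportion, model.weights, (3.0, 9.0), (0.01, 0.15)
        )
        assert res.intercept_a == pytest.approx(a_star, abs=1e-4)
        assert res.slope_b == pytest.approx(b_star, abs=1e-4)

    def test_weight_scaling_invariance(self, pooled_ref):
        model = ns.ExposureResponseModel.from_pooled(pooled_ref, "RT")
        res1 = model.fit()
        scaled = ns.ExposureResponseModel(
            model.nl, model.proportion, 7.5 * model.weights, source="RT"
        ).fit()
        assert scaled.intercept_a == pytest.approx(res1.intercept_a, abs=1e-8)
        assert scaled.slope_b == pytest.approx(res1.slope_b, abs=1e-10)

    def test_insufficient_classes_raise(self):
        with pytest.raises(InsufficientDataError):
            ns.ExposureResponseModel([40, 50], [0.05, 0.08], [100, 100])

    def test_parameter_recovery_unbiased_and_rmse_shrinks(self):
        """Binomial replicates at the observed class sizes center on truth;
        the error shrinks when the class sizes grow."""
        a_true, b_true = ns.REFERENCE_PARAMS["RT"]
        n_small = {k: int(v) for k, v in zip(range(38, 74, 5), (187, 373, 621, 707, 517, 330, 183, 85))}
        n_big = {k: 10 * v for k, v in n_small.items()}

        def replicate(sizes, seed):
            bins = ns.generate_pooled_bins(a_true, b_true, sizes, seed=seed)
            return ns.ExposureResponseModel.from_pooled(bins, "RT").fit().slope_b

        est_small = np.array([replicate(n_small, s) for s in range(200)])
        est_big = np.array([replicate(n_big, s) for s in range(50)])
        # unbiased within Monte-Carlo error (3 SEs of the replicate mean)
        se_mean = est_small.std() / np.sqrt(len(est_small))
        assert abs(est_small.mean() - b_true) < 3 * se_mean + 1e-12
        rmse_small = np.sqrt(np.mean((est_small - b_true) ** 2))
        rmse_big = np.sqrt(np.mean((est_big - b_true) ** 2))
        assert rmse_big < rmse_small


class TestPrediction:
    def test_monotone_increasing_for_positive_slope(self, fits_ref):
        grid = np.arange(33, 79, 1.0)
        for res in fits_ref.values():
            pred = res.predict_pct(grid)
            assert np.all(np.diff(pred) > 0)

    def test_zero_slope_is_constant(self):
        assert logistic_pct(40, 2.0, 0.0) == pytest.approx(logistic_pct(75, 2.0, 0.0))

    def test_prediction_table_shape(self, fits_ref):
        tab = fits_ref["RT"].prediction_table(38, 73, 5)
        assert tab["nl"].tolist() == list(range(38, 74, 5))
        assert set(tab.columns) == {"nl", "pct_hsd", "lci", "uci"}
        fine = fits_ref["RT"].prediction_table(38, 73, 1)
        assert len(fine) == 36


class TestConfidenceBand:
    def test_band_contains_point_estimate(self, fits_ref):
        for res in fits_ref.values():
            grid = np.arange(33, 79, 1.0)
            lo, hi = res.conf_band_pct(grid)
            point = res.predict_pct(grid)
            assert np.all(lo < point) and np.all(point < hi)

    def test_zero_covariance_collapses_band(self, fits_ref):
        res = fits_ref["RT"]
        frozen = ns.ExposureResponseResults(
            model=res.model, method="wnls", params=res.params, cov_params=np.zeros((2, 2))
        )
        lo, hi = frozen.conf_band_pct(53.0)
        assert lo[0] == pytest.approx(hi[0])
        assert lo[0] == pytest.approx(frozen.predict_pct(53.0))

    def test_band_matches_parametric_monte_carlo(self, fits_ref):
        """Resampling (a, b) from the estimated normal reproduces the
        delta-method envelope within Monte-Carlo error."""
        res = fits_ref["RT"]
        rng = np.random.default_rng(123)
        draws = rng.multivariate_normal(res.params, res.cov_params, size=40_000)
        for nl in (43.0, 58.0, 73.0):
            eta = draws[:, 1] * nl - draws[:, 0]
            sim = 100.0 / (1.0 + np.exp(-eta))
            lo, hi = res.conf_band_pct(nl)
            sim_lo, sim_hi = np.percentile(sim, [2.5, 97.5])
            assert lo[0] == pytest.approx(sim_lo, rel=0.05)
            assert hi[0] == pytest.approx(sim_hi, rel=0.05)


class TestWeightedR2:
    def test_perfect_fit_is_one(self):
        p = np.array([0.02, 0.05, 0.1])
        assert weighted_r2(p, p, [100, 200, 300]) == pytest.approx(1.0)

    def test_weighted_mean_fit_is_zero(self):
        p = np.array([0.02, 0.05, 0.1])
        w = np.array([100.0, 200, 300])
        pbar = np.sum(w * p) / w.sum()
        assert weighted_r2(p, np.full_like(p, pbar), w) == pytest.approx(0.0)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(FitError):
            weighted_r2([0.1, 0.1], [0.1, 0.1], [10, 10])

    def test_can_be_negative_for_terrible_fit(self):
        p = np.array([0.02, 0.05, 0.1])
        assert weighted_r2(p, p[::-1], [1.0, 1, 1]) < 0
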