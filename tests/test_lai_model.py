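import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from hailcanopy import (
    SENTINEL2_LIKE,
    UAV_LIKE,
    ParametricLAI,
    calibrate_k,
    calibrate_k_gridsearch,
    fvc_to_lai,
    lai_to_ndvi_forward,
    ndvi_to_fvc,
    r_squared,
    rmse,
)
from hailcanopy.lai_model import FVC_CEILING_EPS

S2 = SENTINEL2_LIKE


class TestFvcScaling:
    def test_soil_endpoint_maps_to_zero(self):
        assert ndvi_to_fvc(S2.ndvi_soil, S2) == 0.0
        assert ndvi_to_fvc(-0.2, S2) == 0.0

    def test_midpoint_hand_arithmetic(self):
        # (0.535 - 0.15) / (0.92 - 0.15) = 0.5
        assert ndvi_to_fvc(0.535, S2) == pytest.approx(0.5)

    def test_above_veg_clips_to_ceiling(self):
        assert ndvi_to_fvc(0.99, S2) == pytest.approx(1 - FVC_CEILING_EPS)


class TestBeerLambertInversion:
    def test_zero_cover_zero_lai(self):
        assert fvc_to_lai(0.0, S2) == 0.0

    def test_half_cover_hand_arithmetic(self):
        # -ln(0.5)/0.59
        assert fvc_to_lai(0.5, S2) == pytest.approx(1.1748, abs=1e-4)

    def test_uav_round_trip_identity(self):
        fvc = 1 - np.exp(-0.37 * 3.0)
        assert fvc_to_lai(fvc, UAV_LIKE) == pytest.approx(3.0, abs=1e-9)

    def test_full_cover_rejected(self):
        with pytest.raises(ValueError):
            fvc_to_lai(1.0, S2)


class TestForwardModel:
    def test_bare_soil(self):
        assert lai_to_ndvi_forward(0.0, S2) == pytest.approx(S2.ndvi_soil)

    def test_asymptote(self):
        assert lai_to_ndvi_forward(100.0, S2) == pytest.approx(S2.ndvi_veg, abs=1e-9)
        assert lai_to_ndvi_forward(8.0, S2) < S2.ndvi_veg

    @pytest.mark.parametrize("lai", [0.5, 2.0, 5.0])
    @pytest.mark.parametrize("spec", [S2, UAV_LIKE], ids=lambda s: s.name)
    def test_composition_identity(self, lai, spec):
        back = fvc_to_lai(ndvi_to_fvc(lai_to_ndvi_forward(lai, spec), spec), spec)
        assert back == pytest.approx(lai, abs=1e-9)

    def test_retrieval_monotone_over_real_line(self):
        ndvi = np.linspace(-1, 1.2, 500)
        lai = fvc_to_lai(ndvi_to_fvc(ndvi, S2), S2)
        assert np.all(np.diff(lai) >= 0)
        assert np.all(lai[ndvi <= S2.ndvi_soil] == 0)

    def test_saturation_slope_increases_near_veg_endpoint(self):
        ndvi = np.linspace(0.3, 0.9, 200)
        lai = fvc_to_lai(ndvi_to_fvc(ndvi, S2), S2)
        slope = np.diff(lai)
        assert np.all(np.diff(slope) > 0)  # d(LAI)/d(NDVI) grows toward saturation


class TestCalibration:
    @pytest.mark.parametrize("spec", [S2, UAV_LIKE], ids=lambda s: s.name)
    def test_noise_free_exact_recovery(self, spec):
        lai = np.array([0.5, 1.0, 2.0, 3.0, 4.5])
        ndvi = lai_to_ndvi_forward(lai, spec)
        res = calibrate_k(np.column_stack([ndvi, lai]), spec.ndvi_soil, spec.ndvi_veg)
        assert res.k_hat == pytest.approx(spec.k_theta, abs=1e-6)
        assert res.rmse == pytest.approx(0.0, abs=1e-9)
        assert res.n == 5

    def test_single_pair_closed_form(self):
        # c = -ln(1-FVC) = 0.6931 when FVC = 0.5; k = c^2 / (c*lai) = c / lai
        ndvi = 0.535  # FVC 0.5 under default endpoints
        res = calibrate_k([(ndvi, 1.0)])
        assert res.k_hat == pytest.approx(0.6931, abs=1e-4)

    @pytest.mark.parametrize("k_true", [0.59, 0.37])
    def test_noisy_consistency(self, k_true):
        rng = np.random.default_rng(314)
        spec = S2.with_k(k_true)
        lai = rng.uniform(0.3, 5.5, 200)
        ndvi = lai_to_ndvi_forward(lai, spec)
        noisy = np.clip(lai + rng.normal(0, 0.3, 200), 0.01, None)
        res = calibrate_k(np.column_stack([ndvi, noisy]))
        assert abs(res.k_hat - k_true) < 0.05

    def test_no_vegetation_signal_rejected(self):
        with pytest.raises(ValueError, match="vegetation signal"):
            calibrate_k([(0.05, 1.0), (0.10, 2.0)])

    def test_nonpositive_cross_moment_rejected(self):
        with pytest.raises(ValueError, match="cross-moment"):
            calibrate_k([(0.5, -3.0)])

    def test_closed_form_matches_grid_oracle(self):
        """Closed-form minimiser agrees with brute-force grid search."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lai = rng.uniform(0.2, 6.0, 30)
            k_true = rng.uniform(0.3, 0.9)
            ndvi = lai_to_ndvi_forward(lai, S2.with_k(k_true))
            noisy = np.clip(lai + rng.normal(0, 0.4, 30), 0.01, None)
            pairs = np.column_stack([ndvi, noisy])
            k_closed = calibrate_k(pairs).k_hat
            k_grid = calibrate_k_gridsearch(pairs)
            assert abs(k_closed - k_grid) <= 1e-4


class TestFitMetrics:
    def test_rmse_zero_iff_identical(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1, 3, 5], [2, 3, 4]) == pytest.approx(0.8165, abs=1e-4)

    def test_rmse_permutation_invariant(self):
        est, obs = np.array([1.0, 3.0, 5.0]), np.array([2.0, 3.0, 4.0])
        perm = [2, 0, 1]
        assert rmse(est, obs) == pytest.approx(rmse(est[perm], obs[perm]))

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    def test_r2_perfect_linear_relation(self):
        est = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(est, 2.5 * est - 1.0) == pytest.approx(1.0)

    def test_r2_hand_pearson(self):
        # pearson r of (1,2,3) vs (1,2,4) is 0.9820; squared 0.9643
        assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9643, abs=1e-4)

    def test_r2_null_distribution(self):
        rng = np.random.default_rng(7)
        assert r_squared(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_r2_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSklearnInterface:
    def test_fit_predict_and_fitted_attributes(self):
        lai = np.array([0.5, 1.5, 3.0, 4.0])
        ndvi = lai_to_ndvi_forward(lai, S2)
        est = ParametricLAI().fit(ndvi, lai)
        assert est.k_ == pytest.approx(0.59, abs=1e-9)
        assert est.n_ == 4 and est.rmse_ == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(est.predict(ndvi), lai, atol=1e-9)

    def test_column_vector_input_accepted(self):
        lai = np.array([1.0, 2.0, 3.0])
        X = lai_to_ndvi_forward(lai, S2).reshape(-1, 1)
        est = ParametricLAI().fit(X, lai)
        np.testing.assert_allclose(est.predict(X), lai, atol=1e-9)

    def test_frozen_k_is_not_refit(self):
        est = ParametricLAI(k=0.5).fit([0.6, 0.8], [1.0, 9.0])
        assert est.k_ == 0.5

    def test_predict_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            ParametricLAI().predict([0.5])

    def test_get_set_params_and_clone(self):
        est = ParametricLAI(ndvi_soil=0.1, ndvi_veg=0.9, k=0.4)
        params = est.get_params()
        assert params == {"ndvi_soil": 0.1, "ndvi_veg": 0.9, "k": 0.4}
        cl = clone(est)
        assert cl.get_params() == params
        est.set_params(k=None)
        assert est.k is None
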