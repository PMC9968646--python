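import numpy as np
import pandas as pd
import pytest

from hailcanopy import (
    SENTINEL2_LIKE,
    ReflectanceRaster,
    SeasonConfig,
    compare_treatments,
    damage_map,
    generate_experiment,
    percent_variation,
    run_calibration_validation,
    survey_summary,
)


class TestPercentVariation:
    @pytest.mark.parametrize(
        "treat,ctrl,expected",
        [
            (0.41, 0.62, -33.9),  # strongest early drop, satellite
            (0.27, 0.49, -44.9),  # strongest early drop, UAV
            (0.62, 0.62, 0.0),
            (0.81, 0.80, 1.3),  # 1.25 rounds away from zero
            (0.79, 0.80, -1.3),  # -1.25 rounds away from zero
        ],
    )
    def test_values(self, treat, ctrl, expected):
        assert percent_variation(treat, ctrl) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_variation(0.5, 0.0)


class TestCompareTreatments:
    def _frame(self, groups):
        rows = [{"group": g, "value": v} for g, vals in groups.items() for v in vals]
        return pd.DataFrame(rows)

    def test_identical_values_nothing_flagged(self):
        df = self._frame({"A": [1.0, 1.0, 1.0], "B": [1.0, 1.0, 1.0]})
        out = compare_treatments(df)
        assert not out["significant"].any()

    def test_separated_groups_flagged(self):
        df = self._frame({"A": [1.0, 1.1, 0.9], "B": [5.0, 5.1, 4.9]})
        out = compare_treatments(df)
        assert out.loc[0, "significant"]
        assert out.loc[0, "p_value"] < 0.001

    def test_flags_invariant_under_relabeling(self):
        groups = {"A": [1.0, 1.2, 0.8], "B": [2.0, 2.1, 1.9], "C": [5.0, 5.2, 4.8]}
        out1 = compare_treatments(self._frame(groups))
        renamed = {"C": groups["A"], "B": groups["B"], "A": groups["C"]}
        out2 = compare_treatments(self._frame(renamed))
        sig1 = {frozenset((r.group1, r.group2)): r.significant for r in out1.itertuples()}
        relabel = {"A": "C", "B": "B", "C": "A"}
        sig2 = {
            frozenset((relabel[r.group1], relabel[r.group2])): r.significant
            for r in out2.itertuples()
        }
        assert sig1 == sig2

    def test_single_replicate_group_excluded_with_warning(self):
        df = self._frame({"A": [1.0, 1.1], "B": [2.0, 2.1], "C": [9.0]})
        with pytest.warns(UserWarning, match="single replicate"):
            out = compare_treatments(df)
        assert set(out["group1"]) | set(out["group2"]) == {"A", "B"}

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_treatments(self._frame({"A": [1.0, 2.0]}))


class TestDamageMap:
    def _raster(self, values, mask=None):
        values = np.asarray(values, dtype=float)
        if mask is None:
            mask = np.zeros_like(values, dtype=bool)
        return ReflectanceRaster(values, mask, origin=(0, 100), pixel_size=(10, 10))

    def test_reference_pixel_maps_to_zero(self):
        out = damage_map(self._raster(np.full((3, 3), 6.0)), ctrl_reference=6.0)
        assert np.all(out.values == 0.0)

    def test_half_reference_is_minus_fifty(self):
        out = damage_map(self._raster(np.full((2, 2), 3.0)), ctrl_reference=6.0)
        assert np.all(out.values == -50.0)

    def test_nodata_propagates(self):
        mask = np.ones((2, 2), dtype=bool)
        out = damage_map(self._raster(np.zeros((2, 2)), mask), ctrl_reference=2.0)
        assert out.nodata_mask.all()

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            damage_map(self._raster(np.ones((2, 2))), ctrl_reference=0.0)


@pytest.fixture(scope="module")
def low_noise_bundles():
    kwargs = dict(ndvi_noise_sd=0.002, spatial_cv=0.01, lai_noise_sd=0.01,
                  par_noise_sd_frac=0.002)
    b1 = generate_experiment(
        SeasonConfig.year1(seed=21, **kwargs), "year1", sensors=(SENTINEL2_LIKE,)
    )
    b2 = generate_experiment(
        SeasonConfig.year2(seed=22, **kwargs), "year2", sensors=(SENTINEL2_LIKE,)
    )
    return b1, b2


class TestCalibrationValidationWorkflow:

    def test_low_noise_recovery_and_validation(self, low_noise_bundles):
        cal, val = run_calibration_validation(*low_noise_bundles, "satellite")
        assert abs(cal.k_hat - 0.59) < 0.02
        assert val.rmse < 0.3

    def test_validation_never_updates_k(self, low_noise_bundles):
        cal, val = run_calibration_validation(*low_noise_bundles, "satellite")
        assert val.k_hat == cal.k_hat

    def test_more_ground_noise_worsens_validation(self):
        def val_rmse(lai_sd):
            b1 = generate_experiment(
                SeasonConfig.year1(seed=33, lai_noise_sd=lai_sd), "year1",
                sensors=(SENTINEL2_LIKE,),
            )
            b2 = generate_experiment(
                SeasonConfig.year2(seed=34, lai_noise_sd=lai_sd), "year2",
                sensors=(SENTINEL2_LIKE,),
            )
            return run_calibration_validation(b1, b2, "satellite")[1].rmse

        assert val_rmse(0.6) > val_rmse(0.1)


class TestSurveySummary:
    def test_noiseless_summary_reproduces_configured_defoliation(self):
        """With zero noise, treatment percent variations follow from the
        configured defoliation fractions through the forward model."""
        cfg = SeasonConfig(seed=0, ndvi_noise_sd=0.0, spatial_cv=0.0,
                           lai_noise_sd=0.0, par_noise_sd_frac=0.0,
                           survey_dates=("2021-08-25",))
        bundle = generate_experiment(cfg, "year2", sensors=(SENTINEL2_LIKE,))
        summ = survey_summary(bundle, "satellite")
        from hailcanopy import control_lai, lai_to_ndvi_forward

        ctrl_ndvi = lai_to_ndvi_forward(control_lai("2021-08-25", cfg), SENTINEL2_LIKE)
        for _, row in summ[summ.stage == "M"].iterrows():
            frac = cfg.defoliation_fraction[row.intensity]
            lai_t = control_lai("2021-08-25", cfg) * (1 - frac)
            expected = percent_variation(
                lai_to_ndvi_forward(lai_t, SENTINEL2_LIKE), ctrl_ndvi
            )
            assert row.pct_vs_ctrl == pytest.approx(expected, abs=0.1)

    def test_ctrl_rows_have_zero_pct(self, fast_season):
        bundle = generate_experiment(fast_season, "year2", sensors=(SENTINEL2_LIKE,))
        summ = survey_summary(bundle, "satellite")
        assert (summ.loc[summ.stage == "CTRL", "pct_vs_ctrl"] == 0.0).all()

    def test_pct_sign_matches_mean_difference(self, fast_season):
        bundle = generate_experiment(fast_season, "year2", sensors=(SENTINEL2_LIKE,))
        summ = survey_summary(bundle, "satellite")
        ctrl = summ.loc[summ.stage == "CTRL", "mean_ndvi"].iloc[0]
        treated = summ[summ.stage != "CTRL"]
        nonzero = treated[treated.pct_vs_ctrl != 0]
        assert (np.sign(nonzero.pct_vs_ctrl) == np.sign(nonzero.mean_ndvi - ctrl)).all()
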