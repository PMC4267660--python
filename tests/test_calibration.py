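"""Forster calibration fitting and efficiency/distance inversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.base import clone

from rnafret.calibration import (
    CalibrationModel,
    FoersterCalibration,
    RulerGeometry,
    distance_from_efficiency,
    efficiency_from_distance,
    fit_calibration,
    ruler_separation,
)
from rnafret.simulate import simulate_calibration_dataset


class TestRulerSeparation:
    @pytest.mark.parametrize(
        "bp,with_linker,expected",
        [(45, False, 15.3), (10, False, 3.4), (10, True, 4.9)],
    )
    def test_separations(self, bp, with_linker, expected):
        geom = RulerGeometry(include_linker_in_abscissa=with_linker)
        assert ruler_separation(bp, geom) == pytest.approx(expected)

    def test_non_positive_bp_rejected(self):
        with pytest.raises(ValueError):
            ruler_separation(0)


class TestForsterCurve:
    def test_half_transfer_at_r_eff(self, calibration_model):
        assert efficiency_from_distance(8.5, calibration_model) == pytest.approx(0.5)

    def test_contact_limit(self, calibration_model):
        assert efficiency_from_distance(0.0, calibration_model) == pytest.approx(1.0)

    def test_direct_evaluation(self, calibration_model):
        # (6.5/8.5)^6 ~ 0.200
        assert efficiency_from_distance(6.5, calibration_model) == pytest.approx(
            0.83335, abs=1e-4
        )

    def test_strictly_decreasing_in_distance(self, calibration_model):
        r = np.linspace(0.0, 30.0, 200)
        e = efficiency_from_distance(r, calibration_model)
        assert np.all(np.diff(e) < 0)


class TestDistanceInversion:
    def test_half_point_inverts_to_r_eff(self, calibration_model):
        R, _ = distance_from_efficiency(0.5, 0.0, calibration_model)
        assert R == pytest.approx(8.5, rel=1e-12)

    def test_direct_evaluation(self, calibration_model):
        R, _ = distance_from_efficiency(0.2, 0.0, calibration_model)
        assert R == pytest.approx(8.5 * 4 ** (1 / 6), rel=1e-9)

    @given(st.floats(min_value=0.5, max_value=25.0))
    def test_round_trip_identity(self, r):
        model = CalibrationModel(r_eff=8.5)
        e = efficiency_from_distance(r, model)
        back, _ = distance_from_efficiency(e, 0.0, model)
        assert back == pytest.approx(r, rel=1e-9)

    @given(st.floats(min_value=0.01, max_value=0.98))
    def test_inversion_decreasing_in_efficiency(self, e):
        model = CalibrationModel(r_eff=8.5)
        r1, _ = distance_from_efficiency(e, 0.0, model)
        r2, _ = distance_from_efficiency(e + 0.01, 0.0, model)
        assert r2 < r1

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_uninvertible_efficiency_rejected(self, bad, calibration_model):
        with pytest.raises(ValueError, match="invert"):
            distance_from_efficiency(bad, 0.0, calibration_model)

    def test_uncertainty_combines_both_sources(self):
        exact = CalibrationModel(r_eff=8.5, sigma_r_eff=0.0)
        fuzzy = CalibrationModel(r_eff=8.5, sigma_r_eff=0.9)
        _, s1 = distance_from_efficiency(0.5, 0.03, exact)
        _, s2 = distance_from_efficiency(0.5, 0.03, fuzzy)
        assert s2 > s1 > 0
        # at E=0.5 the r_eff contribution alone is R/r_eff * sigma = 0.9
        _, s3 = distance_from_efficiency(0.5, 0.0, fuzzy)
        assert s3 == pytest.approx(0.9, rel=1e-6)


class TestFitCalibration:
    def test_noise_free_recovery_to_1e6(self):
        df = simulate_calibration_dataset(r_eff=8.5, noise_sd_E=0.0)
        model = fit_calibration(df[["R_nm", "E", "sigma_E"]])
        assert abs(model.r_eff - 8.5) / 8.5 < 1e-6

    def test_noise_free_residuals_vanish(self):
        df = simulate_calibration_dataset(r_eff=7.0, noise_sd_E=0.0)
        model = fit_calibration(df[["R_nm", "E", "sigma_E"]])
        pred = efficiency_from_distance(df["R_nm"].to_numpy(), model)
        np.testing.assert_allclose(pred, df["E"], atol=1e-8)

    def test_single_half_point_exactly_determined_with_warning(self):
        with pytest.warns(UserWarning, match="determined|under-constrained"):
            model = fit_calibration([(8.5, 0.5, 0.0)])
        assert model.r_eff == pytest.approx(8.5, rel=1e-6)

    def test_identical_separations_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_calibration([(8.5, 0.5, 0.01), (8.5, 0.4, 0.01), (8.5, 0.6, 0.01)])

    def test_sigma_r_eff_monotone_in_linker_uncertainty(self):
        df = simulate_calibration_dataset(r_eff=8.5, noise_sd_E=0.03, seed=2)
        sigmas = []
        for u in (0.0, 0.10, 0.30):
            geom = RulerGeometry(linker_rel_uncertainty=u)
            sigmas.append(fit_calibration(df[["R_nm", "E", "sigma_E"]], geom).sigma_r_eff)
        assert sigmas[0] <= sigmas[1] <= sigmas[2]

    def test_abscissa_convention_shifts_r_eff(self):
        # same efficiencies placed at linker-shifted separations fit a larger r_eff
        base = simulate_calibration_dataset(r_eff=8.5, noise_sd_E=0.0)
        shifted = base.copy()
        shifted["R_nm"] = shifted["R_nm"] + 1.5
        m0 = fit_calibration(base[["R_nm", "E", "sigma_E"]])
        m1 = fit_calibration(shifted[["R_nm", "E", "sigma_E"]])
        assert m1.r_eff > m0.r_eff

    def test_estimator_clone_and_params_round_trip(self):
        est = FoersterCalibration(linker_rel_uncertainty=0.2, r_eff_init=9.0)
        params = est.get_params()
        assert params["linker_rel_uncertainty"] == 0.2
        cloned = clone(est)
        assert cloned.get_params() == params
        df = simulate_calibration_dataset(r_eff=8.5, noise_sd_E=0.0)
        cloned.fit(df["R_nm"], df["E"])
        assert cloned.r_eff_ == pytest.approx(8.5, rel=1e-6)
        np.testing.assert_allclose(cloned.predict([8.5]), [0.5], atol=1e-6)
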