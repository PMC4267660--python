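"""Worm-like-chain density, moments, contour inversion, width prediction."""

import numpy as np
import pytest
from scipy import integrate

from rnafret.bursts import shot_noise_fwhm
from rnafret.polymer import (
    PolymerParams,
    infer_persistence_length,
    invert_contour_length,
    predict_fret_histogram,
    rigid_contour_nt,
    sample_wlc,
    wlc_mean,
    wlc_mode,
    wlc_pdf,
    wlc_rms,
)


class TestRigidContour:
    @pytest.mark.parametrize("d,expected", [(9.0, 16), (5.0, 9), (0.59, 1)])
    def test_ceil_conversion(self, d, expected):
        assert rigid_contour_nt(d).L_nt == expected

    def test_rounding_conventions(self):
        d = 9.0  # 15.25 nt
        assert rigid_contour_nt(d, PolymerParams(rounding="floor")).L_nt == 15
        assert rigid_contour_nt(d, PolymerParams(rounding="nearest")).L_nt == 15

    def test_ceil_bracketing_invariant(self):
        params = PolymerParams()
        for d in np.linspace(0.3, 20.0, 50):
            n = rigid_contour_nt(d, params).L_nt
            assert n * params.rise_per_nt >= d - 1e-9
            assert (n - 1) * params.rise_per_nt < d + 1e-9

    def test_non_positive_distance_rejected(self):
        with pytest.raises(ValueError):
            rigid_contour_nt(0.0)


class TestWlcPdf:
    @pytest.mark.parametrize("L,lp", [(5.0, 2.1), (21.0, 2.1), (59.0, 2.1), (9.0, 20.0)])
    def test_normalization(self, L, lp):
        grid = np.linspace(0.0, L, 50_001)[1:-1]
        total = np.trapezoid(wlc_pdf(grid, L, lp), grid)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonnegative_with_support_inside_0_L(self):
        L = 12.0
        grid = np.linspace(-1.0, L + 1.0, 1001)
        dens = np.array([wlc_pdf(max(r, 0.0), L, 2.1) for r in grid])
        assert np.all(dens >= 0)
        assert wlc_pdf(L, L, 2.1) == 0.0
        assert wlc_pdf(L + 0.5, L, 2.1) == 0.0

    def test_rigid_limit_mode_approaches_contour_length(self):
        L = 9.0
        assert wlc_mode(L, 1000.0) == pytest.approx(L, rel=0.01)

    def test_gaussian_coil_limit_rms(self):
        # L = 100 lp: rms of the density approaches sqrt(2 lp L) within 5%
        L, lp = 210.0, 2.1
        grid = np.linspace(0.0, L, 200_001)[1:-1]
        p = wlc_pdf(grid, L, lp)
        rms = np.sqrt(np.trapezoid(grid**2 * p, grid))
        assert rms == pytest.approx(np.sqrt(2 * lp * L), rel=0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            wlc_pdf(1.0, -5.0, 2.1)
        with pytest.raises(ValueError):
            wlc_pdf(1.0, 5.0, 0.0)

    def test_gaussian_form_normalized(self):
        L, lp = 30.0, 2.1
        grid = np.linspace(0.0, L, 50_001)[1:-1]
        total = np.trapezoid(wlc_pdf(grid, L, lp, form="gaussian"), grid)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestWlcRms:
    def test_rod_limit_expansion(self):
        lp = 2.1
        L = lp / 100.0
        assert wlc_rms(L, lp) == pytest.approx(L, rel=0.01)

    def test_direct_evaluation_100nt(self):
        assert wlc_rms(59.0, 2.1) == pytest.approx(15.46, abs=0.01)

    def test_monotone_in_both_arguments(self):
        assert wlc_rms(20.0, 2.1) < wlc_rms(30.0, 2.1)
        assert wlc_rms(20.0, 2.1) < wlc_rms(20.0, 4.0)

    def test_below_contour_length(self):
        for L in (1.0, 5.0, 50.0):
            for lp in (0.5, 2.1, 30.0):
                assert wlc_rms(L, lp) < L

    def test_matches_discrete_chain_simulation(self, rng):
        # freely rotating chain with fixed bend angle cos(theta) = exp(-ds/lp)
        # has the WLC tangent correlation exactly; its rms end-to-end distance
        # must match the closed-form moment within 3%
        L, lp = 21.0, 2.1
        n_seg, n_chains = 500, 3000
        ds = L / n_seg
        cos_t = np.exp(-ds / lp)
        sin_t = np.sqrt(1.0 - cos_t**2)
        t = np.zeros((n_chains, 3))
        t[:, 2] = 1.0
        ends = np.zeros((n_chains, 3))
        for _ in range(n_seg):
            ends += ds * t
            # orthonormal frame per chain
            a = np.where(np.abs(t[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
            e1 = np.cross(t, a)
            e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
            e2 = np.cross(t, e1)
            phi = rng.uniform(0.0, 2.0 * np.pi, n_chains)[:, None]
            t = cos_t * t + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)
        rms_mc = np.sqrt(np.mean(np.sum(ends**2, axis=1)))
        assert rms_mc == pytest.approx(wlc_rms(L, lp), rel=0.03)


class TestInvertContourLength:
    def test_rigid_limit_reduces_to_rigid_model(self):
        est = invert_contour_length(9.0, lp=1e6)
        assert est.L_nm == pytest.approx(9.0, rel=1e-3)
        assert est.L_nt == 16

    def test_rms_match_at_study_persistence_length(self):
        est = invert_contour_length(9.0, lp=2.1)
        assert est.L_nm == pytest.approx(21.386, abs=0.01)
        assert est.L_nm / 0.59 == pytest.approx(36.25, abs=0.02)
        assert est.L_nt == 37  # ceil convention
        nearest = invert_contour_length(9.0, lp=2.1, params=PolymerParams(rounding="nearest"))
        assert nearest.L_nt == 36

    @pytest.mark.parametrize("L", [3.0, 10.0, 40.0])
    @pytest.mark.parametrize("lp", [1.0, 2.1, 8.0])
    def test_right_inverse_of_rms(self, L, lp):
        d = wlc_rms(L, lp)
        est = invert_contour_length(d, lp=lp)
        assert est.L_nm == pytest.approx(L, rel=1e-6)

    @pytest.mark.parametrize("statistic", ["mean", "mode"])
    def test_right_inverse_of_numerical_statistics(self, statistic):
        L, lp = 15.0, 2.1
        d = {"mean": wlc_mean, "mode": wlc_mode}[statistic](L, lp)
        est = invert_contour_length(
            d, lp=lp, params=PolymerParams(match_statistic=statistic)
        )
        assert est.L_nm == pytest.approx(L, rel=1e-5)

    def test_agrees_with_dense_grid_search(self):
        lp = 2.1
        L_grid = np.linspace(0.5, 80.0, 16_000)
        rms_grid = np.array([wlc_rms(L, lp) for L in L_grid])
        for d in (3.0, 6.0, 9.0, 12.0):
            L_brute = L_grid[np.argmin(np.abs(rms_grid - d))]
            L_solve = invert_contour_length(d, lp=lp).L_nm
            assert abs(L_solve - L_brute) <= (L_grid[1] - L_grid[0])

    def test_unreachable_distance_rejected(self):
        with pytest.raises(ValueError):
            invert_contour_length(-1.0, lp=2.1)


class TestPredictFretHistogram:
    def test_rigid_chain_width_is_shot_noise_limited(self, calibration_model):
        # rod at L = r_eff so E = 0.5; FWHM equals the binomial limit
        hist = predict_fret_histogram(
            8.5, np.inf, calibration_model, 100, n_draws=60_000, seed=5
        )
        assert hist.fwhm == pytest.approx(shot_noise_fwhm(0.5, 100), rel=0.05)

    def test_width_decreases_with_rigidity_on_stiff_branch(self, calibration_model):
        widths = [
            predict_fret_histogram(15.0, lp, calibration_model, 100, n_draws=40_000, seed=8).fwhm
            for lp in (3.0, 5.0, 10.0, 30.0)
        ]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_large_photon_count_isolates_conformational_width(self, calibration_model):
        # N -> inf: shot noise vanishes, leaving pure chain broadening
        small_n = predict_fret_histogram(
            15.0, 5.0, calibration_model, 50, n_draws=60_000, seed=9
        )
        big_n = predict_fret_histogram(
            15.0, 5.0, calibration_model, 5000, n_draws=60_000, seed=9
        )
        assert big_n.fwhm < small_n.fwhm
        # conformational floor: chain broadening alone
        conf = predict_fret_histogram(
            15.0, 5.0, calibration_model, 500_000, n_draws=60_000, seed=9
        )
        assert big_n.fwhm == pytest.approx(conf.fwhm, rel=0.1)


class TestInferPersistenceLength:
    def test_self_consistent_recovery(self, calibration_model):
        gen = predict_fret_histogram(15.0, 5.0, calibration_model, 100, n_draws=40_000, seed=7)
        res = infer_persistence_length(
            gen.fwhm, gen.mean_E, 15.0, calibration_model, 100, method="mc", seed=11
        )
        assert not res.lower_bound
        assert res.lp_nm == pytest.approx(5.0, rel=0.15)

    def test_shot_noise_width_reports_rigidity_lower_bound(self, calibration_model):
        res = infer_persistence_length(
            shot_noise_fwhm(0.5, 100), 0.5, 8.5, calibration_model, 100,
            method="quadrature",
        )
        assert res.lower_bound
        assert res.lp_nm == res.bracket[1]

    def test_width_below_shot_noise_rejected(self, calibration_model):
        with pytest.raises(ValueError, match="shot-noise"):
            infer_persistence_length(0.05, 0.5, 8.5, calibration_model, 100)


class TestSampler:
    def test_sample_moments_match_density(self, rng):
        L, lp = 15.0, 2.1
        r = sample_wlc(L, lp, 200_000, rng)
        assert r.min() >= 0 and r.max() <= L
        assert np.sqrt(np.mean(r**2)) == pytest.approx(wlc_rms(L, lp), rel=0.01)

    def test_effectively_rigid_regime_returns_contour_length(self, rng):
        r = sample_wlc(5.0, 1e4, 100, rng)
        np.testing.assert_allclose(r, 5.0)
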