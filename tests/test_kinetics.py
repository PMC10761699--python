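import numpy as np
import pytest

from phenogrow import kinetics
from phenogrow.errors import (
    AnalysisError,
    CalibrationError,
    DetectionError,
    FitError,
    PredictionError,
)
from phenogrow.series import CountSeries, GrowthIndexSeries
from phenogrow.simulate import dmem_like, simulate_plate, BLANK_ID
from phenogrow import compute_gi, estimate_background

from conftest import K562_M, K562_Q, SEEDING_DENSITY
from oracles import brute_force_window


def _gi(times, values, well_id="A1"):
    return GrowthIndexSeries(
        well_id=well_id, times=np.asarray(times, float),
        gi=np.asarray(values, float), gi0=float(values[0]), background=0.0,
    )


class TestDetectExponentialWindow:
    def test_exact_linear_series_returns_full_window(self):
        t = np.arange(10) * 6.0
        fit = kinetics.detect_exponential_window(t, 0.03 * t + 1.0)
        assert (fit.i_start, fit.i_end) == (0, 9)
        assert fit.slope == pytest.approx(0.03, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_piecewise_series_selects_exponential_segment(self):
        # lag (flat) - exponential - plateau
        t = np.arange(30) * 6.0
        y = 0.04 * np.clip(t, 48.0, 120.0)
        fit = kinetics.detect_exponential_window(t, y)
        oracle = brute_force_window(t, y)
        assert (fit.i_start, fit.i_end) == (oracle[0], oracle[1])
        assert fit.slope == pytest.approx(oracle[2], rel=1e-9)
        # the selected window sits inside the rising segment
        assert fit.t_start >= 48.0 and fit.t_end <= 120.0

    def test_too_few_points_raises(self):
        with pytest.raises(DetectionError):
            kinetics.detect_exponential_window([0, 6, 12], [1, 2, 3], min_points=4)

    def test_nonfinite_values_dropped_before_search(self):
        t = np.arange(8) * 6.0
        y = 0.05 * t
        y[0] = -np.inf  # e.g. log of GI == 0
        fit = kinetics.detect_exponential_window(t, y)
        assert fit.t_start == 6.0
        assert fit.slope == pytest.approx(0.05, rel=1e-9)

    def test_no_window_reaching_r2_min_raises(self):
        rng = np.random.default_rng(7)
        t = np.arange(6) * 6.0
        with pytest.raises(DetectionError):
            kinetics.detect_exponential_window(t, rng.normal(0, 5, 6), r2_min=0.9999)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_enumeration(self, seed):
        from conftest import random_window_instance

        rng = np.random.default_rng(seed)
        t, y = random_window_instance(rng)
        oracle = brute_force_window(t, y)
        if oracle is None:
            with pytest.raises(DetectionError):
                kinetics.detect_exponential_window(t, y)
            return
        fit = kinetics.detect_exponential_window(t, y)
        assert (fit.i_start, fit.i_end) == (oracle[0], oracle[1])
        assert fit.slope == pytest.approx(oracle[2], rel=1e-9, abs=1e-12)


class TestFitRateInWindow:
    def test_full_range_window_matches_detection(self):
        t = np.arange(10) * 6.0
        y = 0.03 * t - 2.0
        det = kinetics.detect_exponential_window(t, y)
        fit = kinetics.fit_rate_in_window(t, y, (t[0], t[-1]))
        assert fit.slope == pytest.approx(det.slope, rel=1e-12)

    def test_constant_values_slope_zero(self):
        t = np.arange(5) * 6.0
        fit = kinetics.fit_rate_in_window(t, np.full(5, 1.7), (0.0, 24.0))
        assert fit.slope == 0.0
        assert fit.r2 == 1.0

    def test_power_law_chain_rule(self):
        # ln(GI) = m ln(C) + q with exponential C => slope = m * mu_c
        mu, m, q = 0.03, 0.99, -14.6
        t = np.arange(20) * 6.0
        ln_c = np.log(1e5) + mu * t
        ln_gi = m * ln_c + q
        fit = kinetics.fit_rate_in_window(t, ln_gi, (0.0, t[-1]))
        assert fit.slope == pytest.approx(m * mu, rel=1e-9)

    def test_too_few_points_in_window(self):
        with pytest.raises(FitError):
            kinetics.fit_rate_in_window([0, 6, 12], [1, 2, 3], (5.0, 7.0))


class TestCalibration:
    def test_recovers_printed_relation(self, powerlaw_plate):
        _, _, counts, gi = powerlaw_plate
        res = kinetics.characterise_well(gi, counts)
        cal = res.calibration
        assert cal.m == pytest.approx(K562_M, rel=1e-9)
        assert cal.q == pytest.approx(K562_Q, rel=1e-9)
        assert cal.r2 == pytest.approx(1.0, abs=1e-12)

    def test_gi_equal_to_c_gives_identity_calibration(self):
        t = np.arange(0, 168.1, 24.0)
        c = 1e5 * np.exp(0.03 * t)
        gi = _gi(t, c)
        counts = CountSeries("A1", t, c)
        cal = kinetics.fit_calibration(gi, counts, (0.0, 168.0))
        assert cal.m == pytest.approx(1.0, rel=1e-9)
        assert cal.q == pytest.approx(0.0, abs=1e-7)
        assert cal.cf == pytest.approx(1.0, rel=1e-9)

    def test_pairing_respects_alignment_tolerance(self):
        t_gi = np.arange(0, 168.1, 6.0)
        c_of = lambda t: 1e5 * np.exp(0.03 * np.asarray(t))
        gi = _gi(t_gi, 1e-6 * c_of(t_gi))
        # counts offset 3 h from the GI grid: nothing within 1 h
        t_cnt = np.arange(0, 144.1, 24.0) + 3.0
        counts = CountSeries("A1", t_cnt, c_of(t_cnt))
        with pytest.raises(CalibrationError):
            kinetics.fit_calibration(gi, counts, (0.0, 168.0), align_tol=1.0)
        # within tolerance: all count times pair up
        t_cnt2 = np.arange(0, 144.1, 24.0) + 0.5
        counts2 = CountSeries("A1", t_cnt2, c_of(t_cnt2))
        cal = kinetics.fit_calibration(gi, counts2, (0.0, 168.0), align_tol=1.0)
        assert np.isfinite(cal.m)

    def test_nonpositive_gi_pairs_dropped_with_warning(self):
        t = np.arange(0, 96.1, 24.0)
        c = 1e5 * np.exp(0.03 * t)
        gi_vals = 1e-6 * c
        gi_vals[0] = 0.0
        gi = _gi(t, gi_vals)
        counts = CountSeries("A1", t, c)
        with pytest.warns(UserWarning, match="non-positive"):
            cal = kinetics.fit_calibration(gi, counts, (0.0, 96.0))
        assert cal.m == pytest.approx(1.0, rel=1e-6)


class TestConversionFactor:
    def test_identity_and_ratio(self):
        assert kinetics.conversion_factor(0.03, 0.03) == 1.0
        assert kinetics.conversion_factor(0.06, 0.03) == pytest.approx(2.0)

    def test_zero_mu_c_rejected(self):
        with pytest.raises(AnalysisError):
            kinetics.conversion_factor(0.03, 0.0)

    def test_equals_m_on_power_law_data(self, powerlaw_plate):
        _, _, counts, gi = powerlaw_plate
        res = kinetics.characterise_well(gi, counts)
        assert res.calibration.cf == pytest.approx(res.calibration.m, rel=1e-9)


class TestPrediction:
    def test_identity_calibration_returns_gi(self):
        cal = kinetics.Calibration(m=1.0, q=0.0, r2=1.0, cf=1.0, window=(0.0, 48.0))
        gi = _gi([0, 6, 12], [1e5, 2e5, 4e5])
        pred = kinetics.predict_counts(gi, cal)
        np.testing.assert_allclose(pred.cp, gi.gi)

    def test_inverts_seeding_density(self):
        gi_val = np.exp(K562_Q) * SEEDING_DENSITY ** K562_M
        cal = kinetics.Calibration(m=K562_M, q=K562_Q, r2=1.0, cf=K562_M,
                                   window=(0.0, 48.0))
        gi = _gi([6.0, 12.0], [gi_val, gi_val])
        pred = kinetics.predict_counts(gi, cal)
        np.testing.assert_allclose(pred.cp, SEEDING_DENSITY, rtol=1e-9)

    def test_nonpositive_gi_flagged_undefined(self):
        cal = kinetics.Calibration(m=1.0, q=0.0, r2=1.0, cf=1.0, window=(0.0, 48.0))
        pred = kinetics.predict_counts(_gi([0, 6, 12], [1.0, 0.0, 2.0]), cal)
        assert np.isnan(pred.cp[1])
        assert np.isfinite(pred.cp[[0, 2]]).all()

    def test_all_nonpositive_gi_errors(self):
        cal = kinetics.Calibration(m=1.0, q=0.0, r2=1.0, cf=1.0, window=(0.0, 48.0))
        with pytest.raises(PredictionError):
            kinetics.predict_counts(_gi([0, 6], [-1.0, 0.0]), cal)

    def test_predict_mu_c(self):
        assert kinetics.predict_mu_c(0.03, 1.0) == 0.03
        assert kinetics.predict_mu_c(0.06, 2.0) == pytest.approx(0.03)
        with pytest.raises(AnalysisError):
            kinetics.predict_mu_c(0.03, 0.0)


class TestAccuracy:
    def _pred(self, times, cp):
        return kinetics.PredictionResult(
            times=np.asarray(times, float), cp=np.asarray(cp, float)
        )

    def test_perfect_prediction_gives_one(self):
        counts = CountSeries("A1", [0, 24, 48], [1e5, 2e5, 4e5])
        assert kinetics.accuracy(self._pred([0, 24, 48], [1e5, 2e5, 4e5]), counts) == 1.0

    def test_doubled_prediction_gives_two(self):
        counts = CountSeries("A1", [0, 24], [1e5, 2e5])
        assert kinetics.accuracy(self._pred([0, 24], [2e5, 4e5]), counts) == pytest.approx(2.0)

    def test_no_aligned_pairs_errors(self):
        counts = CountSeries("A1", [0.0], [1e5])
        with pytest.raises(AnalysisError):
            kinetics.accuracy(self._pred([50.0], [1e5]), counts)

    def test_self_calibrated_powerlaw_pipeline_is_exact(self, powerlaw_plate):
        _, _, counts, gi = powerlaw_plate
        res = kinetics.characterise_well(gi, counts)
        pred = kinetics.predict_counts(gi, res.calibration, window=res.calibration.window)
        a = kinetics.accuracy(pred, counts, window=res.calibration.window)
        assert a == pytest.approx(1.0, abs=1e-6)


class TestSaturationWindow:
    @pytest.mark.parametrize(
        "mu,K,c0", [(0.03, 2e6, 1e5), (0.05, 1e6, 2e4), (0.02, 5e6, 1e5)]
    )
    def test_detected_window_excludes_saturated_times(self, mu, K, c0):
        # on logistic growth the log-linear window must stop before
        # concentrations approach carrying capacity
        cfg = dmem_like(mu=mu, K=K, c0=c0, duration_days=12.0, n_replicates=1)
        plate = simulate_plate(cfg)
        counts = plate.counts["A1"]
        fit = kinetics.detect_exponential_window(counts.times, np.log(counts.counts))
        in_window = (counts.times >= fit.t_start) & (counts.times <= fit.t_end)
        assert np.all(counts.counts[in_window] <= 0.8 * K)
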