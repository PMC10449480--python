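import numpy as np
import pytest
from scipy import stats

import meltcycle as mc
from meltcycle.melt_fit import R_KCAL

from conftest import GRID, make_curve


class TestTwoStateSignal:
    def test_midpoint_at_tm(self):
        bn, bu = (2.0, 0.1), (10.0, -0.05)
        tm = 61.3
        y = mc.two_state_signal(tm, tm, 75.0, bn, bu)
        mid = 0.5 * ((bn[0] + bn[1] * tm) + (bu[0] + bu[1] * tm))
        assert y == pytest.approx(mid, rel=1e-12)

    def test_native_limit_far_below_tm(self):
        y = mc.two_state_signal(25.0, 64.0, 100.0, (0.0, 0.0), (1.0, 0.0))
        assert abs(y) < 1e-6  # < 1e-6 of unit amplitude

    def test_fraction_matches_direct_exponential(self):
        # Tm = 333.15 K (60 C), dH = 50, evaluated at 335.15 K (62 C)
        f = mc.fraction_unfolded(62.0, 60.0, 50.0)
        expected = 1.0 / (1.0 + np.exp((50.0 / R_KCAL)
                                       * (1.0 / 335.15 - 1.0 / 333.15)))
        assert f == pytest.approx(expected, rel=1e-12)


class TestBoundsDetection:
    def test_bounds_bracket_sigmoid(self):
        # dH = 80 puts the 10%-derivative points ~10 deg either side of Tm
        curve = make_curve(tm=60.0, dh=80.0, bn=(0.0, 0.0), bu=(1.0, 0.0),
                           probe="CD221")
        b = mc.detect_transition_bounds(curve)
        assert b.source == "AUTO"
        assert b.T_low == pytest.approx(50.0, abs=0.8)  # 2 grid steps
        assert b.T_high == pytest.approx(70.0, abs=0.8)

    def test_linear_curve_raises_no_transition(self):
        curve = mc.MeltCurve("w", 0, 1, "b", "CD221", GRID,
                             3.0 + 0.5 * GRID)
        with pytest.raises(mc.NoTransitionError):
            mc.detect_transition_bounds(curve)

    def test_manual_bounds_returned_unchanged(self, clean_curve):
        b = mc.detect_transition_bounds(clean_curve, manual=(48.0, 77.0))
        assert (b.T_low, b.T_high, b.source) == (48.0, 77.0, "MANUAL")


class TestFitTwoState:
    @pytest.mark.parametrize("tm,dh,slopes", [
        (60.0, 80.0, (5.0, 20.0)),
        (55.0, 120.0, (-3.0, 8.0)),
        (70.0, 60.0, (0.0, 0.0)),
    ])
    def test_noise_free_recovery(self, tm, dh, slopes):
        curve = make_curve(tm=tm, dh=dh, bn=(1000.0, slopes[0]),
                           bu=(20000.0, slopes[1]))
        fit = mc.fit_two_state(curve)
        assert fit.converged
        assert fit.Tm == pytest.approx(tm, abs=1e-3)
        assert fit.dH_vH == pytest.approx(dh, rel=1e-3)
        assert fit.bounds.T_low < fit.Tm < fit.bounds.T_high

    def test_noisy_replicates_mean_within_tenth_degree(self):
        tms = [
            mc.fit_two_state(make_curve(tm=64.0, noise_sd=0.02, seed=s)).Tm
            for s in range(6)
        ]
        assert np.mean(tms) == pytest.approx(64.0, abs=0.1)

    def test_flat_curve_errors(self):
        curve = mc.MeltCurve("w", 0, 1, "b", "CD221", GRID,
                             np.full(GRID.size, 5.0))
        with pytest.raises(mc.MeltFitError):
            mc.fit_two_state(curve)

    def test_affine_rescaling_leaves_tm_and_dh(self, clean_curve):
        fit0 = mc.fit_two_state(clean_curve)
        scaled = clean_curve.sorted_copy(
            signals=-0.003 * clean_curve.signals + 7.0, probe="CD221"
        )
        fit1 = mc.fit_two_state(scaled)
        assert fit1.Tm == pytest.approx(fit0.Tm, abs=1e-6)
        assert fit1.dH_vH == pytest.approx(fit0.dH_vH, rel=1e-6)

    def test_dsf_truncated_at_fluorescence_maximum(self):
        cfg = mc.GeneratorConfig(noise_sd=0.0, n_replicates=1,
                                 dsf_quench=0.01)
        ds = mc.generate_plate(mc.make_truth(cfg), cfg, "DSF")
        curve = ds.curves[0]
        trunc = mc.truncate_dsf_peak(curve)
        assert len(trunc) < len(curve)
        # a few quenched points survive before the maximum, so the
        # truncation heuristic is good to a fraction of a degree, not exact
        fit = mc.fit_two_state(curve)
        assert fit.Tm == pytest.approx(64.0, abs=0.3)


class TestRatioMethod:
    def test_symmetric_sigmoid_flat_baselines(self):
        # with pure baseline windows the 0.5 crossing is the midpoint
        curve = make_curve(tm=62.0, dh=100.0, bn=(0.0, 0.0), bu=(1.0, 0.0),
                           probe="CD221")
        b = mc.TransitionBounds(47.0, 77.0, "MANUAL")
        tm = mc.tm_by_ratio(curve, b)
        assert tm == pytest.approx(62.0, abs=0.01)

    @pytest.mark.parametrize("tm", [50.0, 57.0, 64.0, 70.0])
    @pytest.mark.parametrize("dh", [60.0, 80.0, 150.0])
    def test_agrees_with_model_method_noise_free(self, tm, dh):
        """Both Tm estimators agree within one 0.4-degree grid step on
        clean curves whose transitions resolve within the scan."""
        curve = make_curve(tm=tm, dh=dh, bn=(1000.0, 5.0),
                           bu=(20000.0, -5.0), probe="CD221")
        b = mc.detect_transition_bounds(curve)
        assert abs(mc.fit_two_state(curve, b).Tm
                   - mc.tm_by_ratio(curve, b)) <= 0.4

    def test_fraction_monotone_on_clean_curve(self, clean_curve):
        b = mc.detect_transition_bounds(clean_curve)
        T, y = clean_curve.temperatures, clean_curve.signals
        native = T <= b.T_low
        unfolded = T >= b.T_high
        bn = np.polyfit(T[native], y[native], 1)
        bu = np.polyfit(T[unfolded], y[unfolded], 1)
        f = (y - np.polyval(bn, T)) / (np.polyval(bu, T) - np.polyval(bn, T))
        inside = (T >= b.T_low) & (T <= b.T_high)
        assert np.all(np.diff(f[inside]) > -1e-9)

    def test_multiple_crossings_pick_nearest_derivative_peak(self):
        curve = make_curve(tm=64.0, dh=150.0, bn=(0.0, 0.0), bu=(1.0, 0.0),
                           probe="CD221")
        y = curve.signals.copy()
        # wiggle the half-converted region to create three 0.5-crossings
        T = curve.temperatures
        bump = 0.06 * np.exp(-((T - 64.8) / 0.25) ** 2)
        y = y - bump
        wiggly = curve.sorted_copy(signals=y)
        b = mc.detect_transition_bounds(curve)  # clean bounds
        tm = mc.tm_by_ratio(wiggly, b)
        assert tm == pytest.approx(64.0, abs=0.45)

    def test_crossing_never_reached_errors(self):
        curve = make_curve(tm=64.0, dh=80.0, probe="CD221")
        b = mc.TransitionBounds(40.0, 50.0, "MANUAL")  # below the sigmoid
        with pytest.raises(mc.MeltFitError):
            mc.tm_by_ratio(curve, b)


class TestDerivativeShapeStats:
    def test_gaussian_derivative_near_zero_moments(self):
        # a melt whose rate profile is Gaussian has zero skew and excess
        grid = np.arange(25.0, 95.0, 0.4)
        y = stats.norm.cdf(grid, loc=60.0, scale=3.0)
        curve = mc.MeltCurve("w", 0, 1, "b", "CD221", grid, y)
        s = mc.derivative_shape_stats([curve])
        assert abs(s.skewness_mean) < 0.05
        assert abs(s.kurtosis_mean) < 0.1

    def test_skew_normal_peak_matches_moment_oracle(self):
        grid = np.arange(25.0, 95.0, 0.1)
        shape = -5.0
        trace = mc.generate_dsc_like([(64.0, 3.0, shape, 1.0)], grid)
        s = mc.derivative_shape_stats([trace])
        skew_true, kurt_true = stats.skewnorm.stats(shape, moments="sk")
        assert s.skewness_mean == pytest.approx(float(skew_true), abs=0.05)
        assert s.skewness_mean < 0
        assert s.kurtosis_mean == pytest.approx(float(kurt_true), abs=0.1)

    def test_identical_curves_zero_ensemble_sd(self):
        curves = [make_curve(probe="CD221"), make_curve(probe="CD221")]
        s = mc.derivative_shape_stats(curves)
        assert s.skewness_sd == 0.0
        assert s.kurtosis_sd == 0.0

    def test_nonpositive_derivative_curve_skipped(self):
        falling = mc.MeltCurve("w", 0, 1, "b", "CD221", GRID,
                               100.0 - 1.0 * GRID)
        good = make_curve(probe="CD221")
        with pytest.warns(UserWarning, match="skipped"):
            s = mc.derivative_shape_stats([falling, good])
        assert s.n_curves == 1
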