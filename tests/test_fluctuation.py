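"""Variance profiles, peak detection and ensemble classification."""

import numpy as np
import pytest

from g4twist import (PeakDetectionOptions, SimParams, Trace, VarianceProfile,
                     classify_ensemble, detect_characteristic_forces,
                     extension_variance, simulate_trace, validate_classifier,
                     variance_convergence, variance_profile)


def _trace_from(values, rate=300.0):
    values = np.asarray(values, dtype=float)
    return Trace(force=0.5, turns=-40, time=np.arange(values.size) / rate,
                 extension=values, sample_rate=rate)


def _profile(force, variance, window=4.0):
    return VarianceProfile(force=np.asarray(force, float),
                           variance=np.asarray(variance, float),
                           window=window)


class TestExtensionVariance:
    def test_constant_trace_has_zero_variance(self):
        assert extension_variance(_trace_from(np.full(3000, 500.0))) == 0.0

    def test_white_noise_variance_within_sampling_error(self, rng):
        # chi-square sampling error of s^2: SE = sigma^2 * sqrt(2/(n-1))
        n, sd = 10_000, 10.0
        tr = _trace_from(rng.standard_normal(n) * sd)
        se = sd ** 2 * np.sqrt(2.0 / (n - 1))
        assert abs(extension_variance(tr, window=n / 300.0) - sd ** 2) < 3 * se

    def test_balanced_telegraph_gives_quarter_amplitude_squared(self):
        # equal-dwell two-level signal at +/- dL/2: variance -> dL^2/4
        dL = 100.0
        levels = np.tile(np.repeat([dL / 2, -dL / 2], 30), 200)
        v = extension_variance(_trace_from(levels), window=len(levels) / 300.0)
        assert v == pytest.approx(dL ** 2 / 4, rel=1e-3)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            extension_variance(_trace_from(np.zeros(300)), window=2.0)


class TestVarianceConvergence:
    def test_white_noise_curve_is_flat(self, rng):
        tr = _trace_from(rng.standard_normal(3000) * 10.0)
        w, v = variance_convergence(tr)
        assert np.ptp(v) / np.mean(v) < 0.25

    def test_short_trace_rejected(self, rng):
        with pytest.raises(ValueError):
            variance_convergence(_trace_from(rng.standard_normal(300)))

    def test_converges_by_three_seconds_with_default_kinetics(self, cfg_mut):
        """Replicate-averaged variance of a midpoint trace reaches >=95% of
        its asymptote by ~3 s, and grows monotonically in expectation."""
        prm = SimParams(dwell=8.0)
        windows = np.arange(0.5, 8.01, 0.5)
        curves = []
        for i in range(25):
            tr = simulate_trace(prm.F_C2, -40, cfg_mut, prm, False,
                                seed=900 + i)
            curves.append(variance_convergence(tr, windows)[1])
        mean_curve = np.mean(curves, axis=0)
        i3 = np.argmin(np.abs(windows - 3.0))
        assert mean_curve[i3] >= 0.95 * mean_curve[-1]
        # non-decreasing in expectation (small tolerance for residual noise)
        assert np.all(np.diff(mean_curve) > -0.05 * mean_curve[-1])


class TestProfile:
    def test_profile_matches_grid_order_and_length(self, mut_ramp):
        prof = variance_profile(mut_ramp, 4.0)
        assert prof.force.shape == mut_ramp.force_grid.shape
        assert np.array_equal(prof.force, mut_ramp.force_grid)

    def test_constant_ramp_gives_zero_profile(self, cfg_mut, prm):
        from g4twist import simulate_ramp
        ramp = simulate_ramp(-40, cfg_mut, prm, False,
                             force_grid=np.linspace(0.1, 1.0, 10), seed=0)
        for t in ramp.traces:
            t.extension = np.full_like(t.extension, 100.0)
        prof = variance_profile(ramp, 4.0)
        assert np.all(prof.variance == 0)

    def test_simulated_mut_profile_peaks_near_fc2(self, mut_ramp, prm):
        prof = variance_profile(mut_ramp, 4.0)
        assert abs(prof.force[np.argmax(prof.variance)] - prm.F_C2) < 0.05


class TestPeakDetection:
    grid = np.round(np.arange(0.05, 3.0001, 0.01), 10)

    def _bump(self, center, height=1000.0, width=0.05):
        return height * np.exp(-0.5 * ((self.grid - center) / width) ** 2)

    def test_single_constructed_bump(self):
        call = detect_characteristic_forces(
            _profile(self.grid, self._bump(0.69) + 10.0))
        assert call.label == "single"
        assert abs(call.F_C - 0.69) <= 0.01

    def test_double_constructed_bumps_at_the_reported_forces(self):
        var = self._bump(0.37) + self._bump(0.69) + 10.0
        call = detect_characteristic_forces(_profile(self.grid, var))
        assert call.label == "double"
        assert abs(call.F_C1 - 0.37) <= 0.01
        assert abs(call.F_C2 - 0.69) <= 0.01
        assert call.delta_F == pytest.approx(call.F_C2 - call.F_C1)

    def test_flat_profile_is_no_peak(self):
        call = detect_characteristic_forces(
            _profile(self.grid, np.full(self.grid.size, 5.0)))
        assert call.label == "no_peak"

    def test_minor_bump_below_prominence_threshold_ignored(self):
        var = self._bump(0.69) + self._bump(0.37, height=100.0) + 10.0
        call = detect_characteristic_forces(_profile(self.grid, var))
        assert call.label == "single"

    def test_close_peaks_merged_by_separation_rule(self):
        var = self._bump(0.60, width=0.02) + self._bump(0.66, width=0.02) + 10
        call = detect_characteristic_forces(
            _profile(self.grid, var),
            PeakDetectionOptions(smooth_sd=0.0, min_separation=0.10))
        assert call.label == "single"

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError):
            detect_characteristic_forces(
                _profile(np.linspace(0.1, 1, 5), np.ones(5)))


class TestEnsemble:
    def test_all_single_gives_zero_percent(self):
        grid = TestPeakDetection.grid
        bump = 1000 * np.exp(-0.5 * ((grid - 0.69) / 0.05) ** 2) + 10
        profs = [_profile(grid, bump)] * 5
        summary = classify_ensemble(profs)
        assert summary.pct_double == 0.0
        assert summary.se_pct == 0.0
        assert summary.F_C_single_mean == pytest.approx(0.69, abs=0.01)

    def test_binomial_se_matches_monte_carlo(self, rng):
        # SE formula 100*sqrt(p(1-p)/n) against a 1e5-draw binomial
        n, p = 50, 0.3
        draws = rng.binomial(n, p, 100_000) / n
        mc = 100 * np.std(draws)
        formula = 100 * np.sqrt(p * (1 - p) / n)
        assert formula == pytest.approx(mc, rel=0.02)

    def test_classifier_recovers_ground_truth(self, wt_ensemble):
        sens, spec, mis = validate_classifier(wt_ensemble)
        assert sens >= 0.9
        assert spec >= 0.9

    def test_characteristic_forces_unbiased(self, wt_ensemble, prm):
        profs = [variance_profile(r, 4.0) for r in wt_ensemble]
        s = classify_ensemble(profs)
        assert abs(s.F_C1_mean - prm.F_C1) < 1.5 * 0.01
        assert abs(s.F_C2_mean - prm.F_C2) < 1.5 * 0.01

    def test_smoothing_halving_is_stable(self, wt_ensemble):
        profs = [variance_profile(r, 4.0) for r in wt_ensemble]
        p1 = classify_ensemble(profs, PeakDetectionOptions(smooth_sd=0.03))
        p2 = classify_ensemble(profs, PeakDetectionOptions(smooth_sd=0.015))
        assert abs(p1.pct_double - p2.pct_double) < 5.0

    def test_positive_supercoiling_never_calls_double(self, cfg_wt, prm):
        from g4twist import simulate_ensemble
        ramps = simulate_ensemble(25, 40, cfg_wt, prm, seed=17)
        profs = [variance_profile(r, 4.0) for r in ramps]
        assert classify_ensemble(profs).n_double == 0
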