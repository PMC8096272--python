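"""Three-state trace generator: occupancies, means, hopping, ensembles."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import argrelmax

from g4twist import (SimParams, TetherConfig, default_force_grid,
                     mean_extension, mixing_variance, simulate_ensemble,
                     simulate_ramp, simulate_trace, state_occupancies,
                     wlc_extension)
from g4twist.simulate import (calibrate_gain, effective_p_fold,
                              programmed_g4_stabilization)


class TestOccupancies:
    def test_first_transition_midpoint(self, cfg_wt, prm):
        p_P, p_G, p_D = state_occupancies(prm.F_C1, -40, cfg_wt, prm, True)
        assert p_P == pytest.approx(0.5, abs=1e-6)
        assert p_G == pytest.approx(p_P, abs=1e-3)

    def test_single_transition_midpoint_without_g4(self, cfg_mut, prm):
        p_P, p_G, p_D = state_occupancies(prm.F_C2, -40, cfg_mut, prm, False)
        assert p_P == pytest.approx(0.5)
        assert p_D == pytest.approx(0.5)
        assert p_G == 0.0

    def test_high_force_tail_fully_denatured(self, cfg_wt, prm):
        # logistic tail: s2(3.0) = 1/(1+exp(-(3-0.69)/w)); direct evaluation
        expected = 1.0 / (1.0 + np.exp(-(3.0 - prm.F_C2) / prm.transition_width))
        _, _, p_D = state_occupancies(3.0, -40, cfg_wt, prm, True)
        assert p_D > 0.999
        assert p_D == pytest.approx(expected, rel=1e-6)

    @given(st.floats(0.0, 3.0), st.booleans())
    def test_occupancies_form_a_simplex(self, F, g4):
        cfg, prm = TetherConfig(), SimParams()
        p = np.array(state_occupancies(F, -40, cfg, prm, g4))
        assert np.all(p >= 0)
        assert np.sum(p) == pytest.approx(1.0, abs=1e-12)

    def test_positive_turns_stay_plectonemic(self, cfg_wt, prm):
        p_P, p_G, p_D = state_occupancies(1.0, 40, cfg_wt, prm, True)
        assert (p_P, p_G, p_D) == (1.0, 0.0, 0.0)

    def test_negative_force_rejected(self, cfg_wt, prm):
        with pytest.raises(ValueError):
            state_occupancies(-0.1, -40, cfg_wt, prm, True)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            SimParams(transition_width=-0.01)


class TestMeanExtension:
    def test_collapsed_at_low_force(self, cfg_wt, prm):
        assert mean_extension(1e-6, -40, cfg_wt, prm, False) \
            == pytest.approx(0.0, abs=1e-3)

    def test_converges_to_wlc_at_high_force(self, cfg_wt, prm):
        wlc = wlc_extension(3.0, cfg_wt.contour_length,
                            cfg_wt.persistence_length)
        assert mean_extension(3.0, -40, cfg_wt, prm, True) \
            == pytest.approx(wlc, rel=1e-6)

    def test_wt_above_mut_through_the_transition(self, cfg_wt, prm):
        F = np.linspace(0.2, 0.9, 71)
        wt = mean_extension(F, -40, cfg_wt, prm, True)
        mut = mean_extension(F, -40, cfg_wt, prm, False)
        assert np.all(wt >= mut)

    def test_monotone_in_force(self, cfg_wt, prm):
        F = default_force_grid()
        for g4 in (True, False):
            m = mean_extension(F, -40, cfg_wt, prm, g4)
            assert np.all(np.diff(m) >= -1e-9)


class TestNoiselessVarianceProfile:
    def test_mut_profile_has_one_maximum_at_fc2(self, cfg_mut, prm):
        grid = default_force_grid()
        v = mixing_variance(grid, -40, cfg_mut, prm, False,
                            include_noise=False)
        peaks = argrelmax(v)[0]
        assert peaks.size == 1
        assert abs(grid[peaks[0]] - prm.F_C2) <= 0.01 + 1e-9

    def test_wt_profile_has_two_maxima_at_both_forces(self, cfg_wt, prm):
        grid = default_force_grid()
        v = mixing_variance(grid, -40, cfg_wt, prm, True, include_noise=False)
        peaks = grid[argrelmax(v)[0]]
        assert peaks.size == 2
        assert abs(peaks[0] - prm.F_C1) <= 0.01 + 1e-9
        assert abs(peaks[1] - prm.F_C2) <= 0.01 + 1e-9

    def test_positive_turns_profile_is_flat(self, cfg_wt, prm):
        grid = default_force_grid()
        v = mixing_variance(grid, 40, cfg_wt, prm, True, include_noise=False)
        assert np.all(v == 0)


class TestTraceSimulation:
    def test_quiet_single_state_variance_is_noise_floor(self, cfg_wt, prm):
        trace = simulate_trace(3.0, 0, cfg_wt, prm, False, seed=1)
        floor = prm.bead_noise_sd ** 2 + prm.tracking_noise_sd ** 2
        assert np.var(trace.extension, ddof=1) == pytest.approx(floor, rel=0.2)

    def test_midpoint_variance_matches_closed_form(self, cfg_mut):
        """Telegraph mixing variance p(1-p)*dL^2 at p = 1/2, checked against
        a ~1e6-step simulation with the noise terms switched off."""
        prm = SimParams(dwell=3400.0, tracking_noise_sd=0.0,
                        bead_noise_sd=0.0)
        trace = simulate_trace(prm.F_C2, -40, cfg_mut, prm, False, seed=3)
        expected = mixing_variance(prm.F_C2, -40, cfg_mut, prm, False,
                                   include_noise=False)
        assert np.var(trace.extension, ddof=1) == pytest.approx(expected,
                                                                rel=0.05)

    def test_same_seed_is_bit_identical(self, cfg_wt, prm):
        a = simulate_trace(0.5, -40, cfg_wt, prm, True, seed=9)
        b = simulate_trace(0.5, -40, cfg_wt, prm, True, seed=9)
        assert np.array_equal(a.extension, b.extension)

    def test_stationary_mean_matches_occupancy_model(self, cfg_wt):
        prm = SimParams(dwell=60.0)
        trace = simulate_trace(0.5, -40, cfg_wt, prm, True, seed=5)
        target = mean_extension(0.5, -40, cfg_wt, prm, True)
        # sampling error of the mean of a correlated series
        assert np.mean(trace.extension) == pytest.approx(target, abs=30.0)


class TestRampsAndEnsembles:
    def test_default_grid_has_296_points(self):
        grid = default_force_grid()
        assert grid.size == 296
        assert np.allclose(np.diff(grid), 0.01)

    def test_single_force_ramp(self, cfg_wt, prm):
        ramp = simulate_ramp(-40, cfg_wt, prm, True, force_grid=[0.5], seed=1)
        assert len(ramp.traces) == 1

    def test_empty_grid_rejected(self, cfg_wt, prm):
        with pytest.raises(ValueError):
            simulate_ramp(-40, cfg_wt, prm, True, force_grid=[], seed=1)

    def test_flag_constant_across_ramp(self, wt_ramp):
        assert all(t.meta["g4_available"] for t in wt_ramp.traces)

    @pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 50)])
    def test_degenerate_fold_probabilities(self, cfg_wt, p, expected):
        prm = SimParams(dwell=0.01)
        ramps = simulate_ensemble(50, -40, cfg_wt, prm, seed=2,
                                  force_grid=[0.5], p_fold=p)
        assert sum(r.g4_available for r in ramps) == expected

    def test_realized_fraction_within_binomial_band(self, cfg_wt):
        prm = SimParams(dwell=0.01)
        n, p = 2000, 0.35
        ramps = simulate_ensemble(n, -40, cfg_wt, prm, seed=3,
                                  force_grid=[0.5], p_fold=p)
        frac = np.mean([r.g4_available for r in ramps])
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestFoldProbability:
    def test_zero_for_non_negative_turns(self, cfg_wt):
        assert effective_p_fold(0, cfg_wt) == 0.0
        assert effective_p_fold(40, cfg_wt) == 0.0

    def test_reference_condition_is_the_calibrated_value(self, cfg_wt):
        assert effective_p_fold(-40, cfg_wt) == pytest.approx(cfg_wt.p_fold)

    def test_interior_maximum_and_suppression_at_large_underwinding(self,
                                                                    cfg_wt):
        turns = [-10, -30, -40, -70, -100]
        p = [effective_p_fold(t, cfg_wt) for t in turns]
        assert np.argmax(p) == turns.index(-30)
        assert p[turns.index(-100)] < 0.03


class TestCalibration:
    def test_programmed_energy_closed_form(self, prm):
        expected = (prm.plectoneme_slope * prm.turns_per_g4_event
                    * (prm.F_C2 - prm.F_C1)) * 0.14393
        assert programmed_g4_stabilization(prm) == pytest.approx(expected)

    def test_calibrated_params_hit_target(self, prm):
        prm24 = calibrate_gain(prm, 24.0)
        assert programmed_g4_stabilization(prm24) == pytest.approx(24.0)

    def test_noiseless_work_area_recovers_programmed_energy(self, cfg_wt,
                                                            prm):
        """The area between noiseless mean curves matches the programmed
        stabilization within 15% (small logistic-tail cross term)."""
        prm24 = calibrate_gain(prm, 24.0)
        grid = default_force_grid()
        diff = (mean_extension(grid, -40, cfg_wt, prm24, True)
                - mean_extension(grid, -40, cfg_wt, prm24, False))
        area = np.trapezoid(diff, grid) * 0.14393
        assert area == pytest.approx(24.0, rel=0.15)
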