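"""Parameter-recovery experiments on synthetic data.

Each function builds the synthetic inputs, runs the corresponding analysis
exactly as it would run on real data, and returns the recovered numbers.
They are the package's validation harness: the README's worked example and
the reproduction script both call them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .constants import kbt
from .energetics import work_area
from .fluctuation import (PeakDetectionOptions, classify_ensemble,
                          ramp_mean_curve, variance_profile)
from .pipeline import _cohort_mean_curve
from .simulate import (SimParams, TetherConfig, calibrate_gain,
                       simulate_ensemble, simulate_ramp)
from .steepness import fit_logistic, fit_s0_mixture, logistic_extension
from .wlc import MeanCurve, fit_wlc, wlc_extension

__all__ = [
    "synthetic_wlc_curve",
    "wlc_recovery",
    "synthetic_logistic_curve",
    "logistic_recovery",
    "double_peak_percentage",
    "characteristic_force_recovery",
    "mixture_area_recovery",
    "work_area_recovery",
]

#: Untwisted-tether ground truth (wt): contour 2000 nm, persistence 46 nm.
WLC_TRUTH = {"L0": 2000.0, "Lp": 46.0}

#: Logistic ground truths at n_t = -40 for the two constructs. The printed
#: logistic form decreases with force for b > 0, so an increasing curve has
#: b < 0 with ``a`` the high-force plateau.
LOGISTIC_TRUTH = {
    "wt": {"a": 2000.0, "b": -2000.0, "F1": 0.6, "S0": 0.52},
    "mut": {"a": 2000.0, "b": -2000.0, "F1": 0.6, "S0": 0.64},
}

#: S0 mixture weights of the wt-KCl steepness distribution:
#: 63% high-steepness (low S0) / 37% low-steepness (high S0).
MIXTURE_TRUTH = {"weights": (0.63, 0.37), "means": (0.5, 0.9),
                 "sds": (0.08, 0.10)}


def synthetic_wlc_curve(rng: np.random.Generator, L0: float = WLC_TRUTH["L0"],
                        Lp: float = WLC_TRUTH["Lp"], n_points: int = 25,
                        n_average: int = 25) -> MeanCurve:
    """One untwisted mean force–extension curve with measurement noise.

    Per-measurement SD follows the equipartition estimate of the axial
    extension fluctuation, sqrt(k_B T · dLe/dF); the curve emulates an
    average over ``n_average`` repeated measurements (conservative — the
    averages shown in this kind of experiment pool hundreds of curves),
    so each plotted point scatters by SD/sqrt(n_average). The stored
    ``extension_sd`` is the per-measurement SD, as plotted.
    """
    force = np.geomspace(0.03, 3.0, n_points)
    ext = wlc_extension(force, L0, Lp)
    dF = 1e-4
    slope = (wlc_extension(force + dF, L0, Lp) - ext) / dF
    sd = np.sqrt(kbt() * slope)
    noisy = ext + rng.standard_normal(n_points) * sd / np.sqrt(n_average)
    return MeanCurve(force=force, extension_mean=noisy, extension_sd=sd,
                     n_samples=np.full(n_points, n_average))


def wlc_recovery(n_replicates: int = 200, seed: int = 0) -> dict:
    """Refit WLC parameters on noisy synthetic curves; report the medians.

    Returns L0 in μm and Lp in nm (matching how they are usually quoted),
    plus the full per-replicate arrays.
    """
    rng = np.random.default_rng(seed)
    L0s, Lps = [], []
    for _ in range(n_replicates):
        params = fit_wlc(synthetic_wlc_curve(rng))
        L0s.append(params.L0)
        Lps.append(params.Lp)
    L0s, Lps = np.array(L0s), np.array(Lps)
    return {
        "L0_median_um": float(np.median(L0s) / 1000.0),
        "Lp_median_nm": float(np.median(Lps)),
        "L0_nm": L0s,
        "Lp_nm": Lps,
    }


def synthetic_logistic_curve(rng: np.random.Generator, construct: str = "wt",
                             noise_sd: float = 40.0, n_points: int = 60
                             ) -> MeanCurve:
    """A supercoiled mean curve from the logistic truth plus Gaussian noise.

    ``noise_sd`` (nm) is the scatter of a plotted average curve point —
    the per-measurement SD at the transition (~400 nm) divided by the
    ~100 curves entering the average, order 40 nm.
    """
    truth = LOGISTIC_TRUTH[construct]
    force = np.linspace(0.05, 3.0, n_points)
    ext = logistic_extension(force, **truth)
    noisy = ext + rng.standard_normal(n_points) * noise_sd
    return MeanCurve(force=force, extension_mean=noisy)


def logistic_recovery(n_replicates: int = 100, seed: int = 0,
                      construct: str = "wt") -> dict:
    """Refit the logistic steepness on noisy synthetic curves (median S0)."""
    rng = np.random.default_rng(seed)
    s0s = []
    for _ in range(n_replicates):
        curve = synthetic_logistic_curve(rng, construct)
        s0s.append(fit_logistic(curve).S0)
    s0s = np.array(s0s)
    return {"S0_median": float(np.median(s0s)), "S0": s0s,
            "truth": LOGISTIC_TRUTH[construct]["S0"]}


def double_peak_percentage(n_ramps: int = 400, seed: int = 0,
                           construct: str = "wt", ion: str = "KCl",
                           n_t: int = -40, dwell: float = 5.0) -> dict:
    """Simulate an ensemble and report the classified double-peak rate."""
    cfg = TetherConfig(construct=construct, ion=ion)
    prm = SimParams(dwell=dwell)
    ramps = simulate_ensemble(n_ramps, n_t, cfg, prm, seed=seed)
    profiles = [variance_profile(ramp, window=4.0) for ramp in ramps]
    summary = classify_ensemble(profiles)
    true_frac = float(np.mean([r.g4_available for r in ramps]))
    return {"summary": summary, "pct_double": summary.pct_double,
            "p_fold": cfg.p_fold, "true_pct": 100.0 * true_frac}


def characteristic_force_recovery(n_ramps: int = 200, seed: int = 0,
                                  n_t: int = -40, dwell: float = 5.0) -> dict:
    """Peak-detect known double- and single-transition ramps.

    Simulates ``n_ramps`` G4-available wt ramps and the same number of mut
    ramps, classifies each, and reports the mean detected characteristic
    forces per class.
    """
    cfg_wt = TetherConfig(construct="wt", ion="KCl")
    cfg_mut = TetherConfig(construct="mut", ion="KCl")
    prm = SimParams(dwell=dwell)
    ss = np.random.SeedSequence(seed)
    wt_seeds, mut_seeds = ss.spawn(2)
    fc1, fc2, fc_single = [], [], []
    for i, child in enumerate(wt_seeds.spawn(n_ramps)):
        ramp = simulate_ramp(n_t, cfg_wt, prm, True, seed=child)
        call = classify_ensemble([variance_profile(ramp, 4.0)])
        if call.n_double == 1:
            fc1.append(call.F_C1_mean)
            fc2.append(call.F_C2_mean)
    for i, child in enumerate(mut_seeds.spawn(n_ramps)):
        ramp = simulate_ramp(n_t, cfg_mut, prm, False, seed=child)
        call = classify_ensemble([variance_profile(ramp, 4.0)])
        if call.n_single == 1:
            fc_single.append(call.F_C_single_mean)
    return {
        "F_C1_mean": float(np.mean(fc1)),
        "F_C2_mean": float(np.mean(fc2)),
        "F_C_single_mean": float(np.mean(fc_single)),
        "n_double": len(fc1),
        "n_single": len(fc_single),
        "truth": (SimParams().F_C1, SimParams().F_C2),
    }


def mixture_area_recovery(n_samples: int = 10_000, seed: int = 0) -> dict:
    """Draw S0 values at the two-component truth and refit by EM.

    Reports the minor (high-S0) component's relative area in percent.
    """
    rng = np.random.default_rng(seed)
    w = MIXTURE_TRUTH["weights"]
    comp = rng.random(n_samples) < w[1]
    samples = np.where(
        comp,
        rng.normal(MIXTURE_TRUTH["means"][1], MIXTURE_TRUTH["sds"][1],
                   n_samples),
        rng.normal(MIXTURE_TRUTH["means"][0], MIXTURE_TRUTH["sds"][0],
                   n_samples))
    fit = fit_s0_mixture(samples, k=2)
    # minor component = the high-mean one under this truth
    minor_area = fit.weights[1]
    return {"minor_area_pct": 100.0 * float(minor_area), "fit": fit,
            "truth_pct": 100.0 * w[1]}


def work_area_recovery(n_ramps_per_cohort: int = 60, seed: int = 0,
                       target_kcal: float = 24.0, n_t: int = -40,
                       dwell: float = 5.0) -> dict:
    """Measure the work difference between matched wt/mut cohorts.

    The generator is calibrated so its programmed G4 stabilization equals
    ``target_kcal``; the estimate is the area between the cohort mean
    force–extension curves, converted to kcal/mol.
    """
    cfg_wt = TetherConfig(construct="wt", ion="KCl")
    cfg_mut = TetherConfig(construct="mut", ion="KCl")
    prm = calibrate_gain(SimParams(dwell=dwell), target_kcal)
    ss = np.random.SeedSequence(seed)
    wt_seeds, mut_seeds = ss.spawn(2)
    curves_wt = [
        ramp_mean_curve(simulate_ramp(n_t, cfg_wt, prm, True, seed=c), 4.0)
        for c in wt_seeds.spawn(n_ramps_per_cohort)]
    curves_mut = [
        ramp_mean_curve(simulate_ramp(n_t, cfg_mut, prm, False, seed=c), 4.0)
        for c in mut_seeds.spawn(n_ramps_per_cohort)]
    area = work_area(_cohort_mean_curve(curves_wt),
                     _cohort_mean_curve(curves_mut))
    return {"work_area_kcal": float(area), "target_kcal": target_kcal,
            "programmed_kcal": target_kcal}
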