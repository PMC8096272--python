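"""Pipeline orchestration: simulate (or load) → analyze → report.

For each (construct, ion, n_t) condition the pipeline computes per-ramp
variance profiles, peak classifications and logistic steepness fits, then
aggregates them into an ensemble summary and an energy ledger. Reports are
written as TSV plus a machine-readable JSON that is byte-identical under a
fixed seed (no timestamps, sorted keys).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .energetics import build_ledger, work_area
from .fluctuation import (PeakDetectionOptions, classify_ensemble,
                          detect_characteristic_forces, ramp_mean_curve,
                          variance_profile)
from .io import RunConfig, write_ramp
from .simulate import SimParams, TetherConfig, simulate_ensemble
from .steepness import fit_logistic
from .wlc import MeanCurve

__all__ = ["analyze_ramps", "run_pipeline"]

logger = logging.getLogger(__name__)


def _cohort_mean_curve(curves: list[MeanCurve]) -> MeanCurve | None:
    """Average per-ramp mean curves defined on a shared force grid."""
    if not curves:
        return None
    grid = curves[0].force
    stack = np.vstack([c.extension_mean for c in curves])
    sd = np.std(stack, axis=0, ddof=1) if len(curves) > 1 else \
        np.zeros(grid.size)
    return MeanCurve(force=grid.copy(), extension_mean=stack.mean(axis=0),
                     extension_sd=sd,
                     n_samples=np.full(grid.size, len(curves)))


def analyze_ramps(ramps, window: float = 4.0,
                  opts: PeakDetectionOptions | None = None) -> dict:
    """Analyze a list of ramps sharing one condition.

    Returns a dict with the per-ramp table (classification, characteristic
    forces, logistic parameters), the ensemble summary, cohort mean curves
    (double vs non-double) and the work area between them when both cohorts
    are present. Per-ramp failures are recorded and do not stop the run.
    """
    opts = opts or PeakDetectionOptions()
    rows = []
    profiles = []
    curves_double: list[MeanCurve] = []
    curves_other: list[MeanCurve] = []
    s0_by_label: dict[str, list[float]] = {"double": [], "single": []}
    failures = []
    for i, ramp in enumerate(ramps):
        row: dict = {"ramp": i, "turns": ramp.turns}
        if ramp.g4_available is not None:
            row["g4_available"] = ramp.g4_available
        try:
            prof = variance_profile(ramp, window)
            call = detect_characteristic_forces(prof, opts)
            profiles.append(prof)
            row.update(label=call.label, F_C=call.F_C, F_C1=call.F_C1,
                       F_C2=call.F_C2, delta_F=call.delta_F)
            curve = ramp_mean_curve(ramp, window)
            lp = fit_logistic(curve)
            row.update(a=lp.a, b=lp.b, F1=lp.F1, S0=lp.S0)
            if call.label == "double":
                curves_double.append(curve)
                s0_by_label["double"].append(lp.S0)
            else:
                curves_other.append(curve)
                if call.label == "single":
                    s0_by_label["single"].append(lp.S0)
            logger.info("ramp %d: %s F_C=%s F_C1=%s F_C2=%s S0=%.3g",
                        i, call.label, call.F_C, call.F_C1, call.F_C2, lp.S0)
        except Exception as exc:  # per-ramp failure, pipeline continues
            row.update(label="error", error=str(exc))
            failures.append(i)
            logger.error("ramp %d failed: %s", i, exc)
        rows.append(row)

    summary = classify_ensemble(profiles, opts) if profiles else None
    cohort_double = _cohort_mean_curve(curves_double)
    cohort_other = _cohort_mean_curve(curves_other)
    area = None
    if cohort_double is not None and cohort_other is not None:
        area = work_area(cohort_double, cohort_other)
    ledger = None
    if summary is not None and summary.F_C1_mean and summary.F_C2_mean:
        ledger = build_ledger(F_C1=summary.F_C1_mean, F_C2=summary.F_C2_mean,
                              work_area_kcal=area)
    return {
        "per_ramp": rows,
        "summary": summary,
        "cohort_double": cohort_double,
        "cohort_other": cohort_other,
        "work_area_kcal": area,
        "ledger": ledger,
        "failures": failures,
        "s0_by_label": s0_by_label,
    }


def _jsonable(obj):
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return str(obj)


def run_pipeline(config: RunConfig, ramps_by_turns: dict | None = None,
                 save_traces: bool = False) -> dict:
    """Run simulate→analyze→report for every n_t in the config.

    If ``ramps_by_turns`` (mapping n_t → list of ramps) is given those are
    analyzed instead of simulating. Writes per-condition TSVs, a
    ``report.json`` and the resolved config under ``config.out_dir``;
    returns the report dict. The exit-status convention is carried in
    ``report['n_failures']``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = TetherConfig(construct=config.construct, ion=config.ion)
    prm = SimParams(dwell=config.dwell)
    opts = PeakDetectionOptions(config.smooth_sd, config.min_prominence_frac,
                                config.min_separation)
    grid = config.force_grid()

    report: dict = {
        "version": __version__,
        "config": {f.name: getattr(config, f.name)
                   for f in dataclasses.fields(config)},
        "thresholds": dataclasses.asdict(opts),
        "conditions": {},
        "n_failures": 0,
    }
    for n_t in config.turns:
        if ramps_by_turns is not None and n_t in ramps_by_turns:
            ramps = ramps_by_turns[n_t]
        else:
            ramps = simulate_ensemble(config.n_ramps, n_t, cfg, prm,
                                      seed=config.seed + abs(n_t),
                                      force_grid=grid)
        if save_traces:
            for i, ramp in enumerate(ramps):
                write_ramp(ramp, out / f"nt{n_t}" / f"ramp_{i:04d}")
        result = analyze_ramps(ramps, window=config.window, opts=opts)
        pd.DataFrame(result["per_ramp"]).to_csv(
            out / f"per_ramp_nt{n_t}.tsv", sep="\t", index=False)
        cond = {
            "n_t": n_t,
            "summary": _jsonable(result["summary"]),
            "work_area_kcal": result["work_area_kcal"],
            "ledger": _jsonable(result["ledger"]),
            "failures": result["failures"],
        }
        report["conditions"][str(n_t)] = cond
        report["n_failures"] += len(result["failures"])

    config.to_yaml(out / "config_resolved.yaml")
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
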