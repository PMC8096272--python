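"""Trace/ramp file formats and run configuration.

Traces are tab-separated text, two columns ``time_s  extension_nm``, with
``# key=value`` header lines carrying the metadata (force, turns,
construct, ion, seed, sample rate). A ramp is a directory of trace files
plus a ``manifest.yaml`` listing the files, the force grid and the shared
metadata. Everything is plain text and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .simulate import ForceRamp, Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_ramp",
    "read_ramp",
    "RunConfig",
]

_REQUIRED_HEADER = ("force_pN", "turns", "construct", "ion")


class TraceParseError(ValueError):
    """Malformed trace file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def write_trace(trace: Trace, path) -> Path:
    """Write a trace as headered TSV. Returns the path written."""
    path = Path(path)
    meta = trace.meta
    header = {
        "force_pN": repr(float(trace.force)),
        "turns": str(int(trace.turns)),
        "construct": str(meta.get("construct", "unknown")),
        "ion": str(meta.get("ion", "unknown")),
        "seed": str(meta.get("seed", "")),
        "sample_rate_Hz": repr(float(trace.sample_rate)),
    }
    if "g4_available" in meta:
        header["g4_available"] = str(bool(meta["g4_available"]))
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        fh.write("time_s\textension_nm\n")
        for t, x in zip(trace.time, trace.extension):
            fh.write(f"{float(t)!r}\t{float(x)!r}\n")
    return path


def read_trace(path) -> Trace:
    """Read a headered-TSV trace; lossless round-trip with write_trace."""
    path = Path(path)
    header: dict[str, str] = {}
    times: list[float] = []
    exts: list[float] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise TraceParseError(path, line_no,
                                          "header line without key=value")
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TraceParseError(path, line_no,
                                      f"expected 2 columns, got {len(parts)}")
            try:
                times.append(float(parts[0]))
                exts.append(float(parts[1]))
            except ValueError as exc:
                raise TraceParseError(path, line_no, str(exc)) from None
    for key in _REQUIRED_HEADER:
        if key not in header:
            raise TraceParseError(path, 0, f"missing required header '{key}'")
    meta = {"construct": header["construct"], "ion": header["ion"]}
    if header.get("seed"):
        meta["seed"] = header["seed"]
    if "g4_available" in header:
        meta["g4_available"] = header["g4_available"] == "True"
    sample_rate = float(header.get("sample_rate_Hz", 300.0))
    return Trace(force=float(header["force_pN"]), turns=int(header["turns"]),
                 time=np.array(times), extension=np.array(exts),
                 sample_rate=sample_rate, meta=meta)


def write_ramp(ramp: ForceRamp, directory) -> Path:
    """Write a ramp as one trace file per force plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for i, trace in enumerate(ramp.traces):
        name = f"trace_{i:04d}.tsv"
        write_trace(trace, directory / name)
        files.append(name)
    manifest = {
        "turns": int(ramp.turns),
        "force_grid_pN": [float(f) for f in ramp.force_grid],
        "files": files,
        "construct": ramp.meta.get("construct", "unknown"),
        "ion": ramp.meta.get("ion", "unknown"),
    }
    if ramp.g4_available is not None:
        manifest["g4_available"] = bool(ramp.g4_available)
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return directory


def read_ramp(directory) -> ForceRamp:
    """Read a ramp directory written by :func:`write_ramp`."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    traces = [read_trace(directory / name) for name in manifest["files"]]
    return ForceRamp(
        traces=traces,
        force_grid=np.array(manifest["force_grid_pN"], dtype=float),
        turns=int(manifest["turns"]),
        g4_available=manifest.get("g4_available"),
        meta={"construct": manifest.get("construct"),
              "ion": manifest.get("ion")})


@dataclass
class RunConfig:
    """Validated configuration of a simulate→analyze→report run.

    Unknown keys in a config file are rejected; every run writes its
    resolved configuration next to its outputs.
    """

    construct: str = "wt"
    ion: str = "KCl"
    turns: list = field(default_factory=lambda: [-40])
    n_ramps: int = 50
    force_min: float = 0.05
    force_max: float = 3.0
    force_step: float = 0.01
    window: float = 4.0
    dwell: float = 5.0
    smooth_sd: float = 0.03
    min_prominence_frac: float = 0.25
    min_separation: float = 0.10
    seed: int = 0
    out_dir: str = "g4twist_run"

    def __post_init__(self) -> None:
        if self.construct not in ("wt", "mut"):
            raise ValueError("construct must be 'wt' or 'mut'")
        if self.ion not in ("KCl", "NaCl", "LiCl"):
            raise ValueError("ion must be KCl, NaCl or LiCl")
        if self.n_ramps < 1:
            raise ValueError("n_ramps must be >= 1")
        if not (self.force_min < self.force_max and self.force_step > 0):
            raise ValueError("invalid force grid specification")
        if self.window > self.dwell:
            raise ValueError("analysis window cannot exceed the dwell")
        self.turns = [int(t) for t in self.turns]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def force_grid(self) -> np.ndarray:
        n = int(round((self.force_max - self.force_min) / self.force_step)) + 1
        return np.linspace(self.force_min, self.force_max, n)
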