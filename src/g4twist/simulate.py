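"""Synthetic magnetic-tweezers traces for a negatively supercoiled DNA tether.

The generator emulates the experiment this package analyses: a torsionally
constrained ~6.7 kb dsDNA tether held at fixed force F and fixed imposed
turns n_t, whose end-to-end extension is tracked at 300 Hz. Under negative
supercoiling the tether relaxes torsion either by plectonemes (short) or by
a denaturation bubble (extended); a G-quadruplex-forming promoter region can
open first, absorbing ~7 turns at a lower force.

Occupancy model (phenomenological, sequential two-logistic):

  P (plectonemic)  --F_C1-->  G (G4 intermediate)  --F_C2-->  D (bubble)

with logistic weights s1, s2 of width ``transition_width``. When the G4
pathway is unavailable (mutant construct, inhibiting ion, positive turns)
the P->D transition is a single logistic at F_C2. Mean extension is the
occupancy-weighted mix of three levels built on the worm-like chain.

Fluctuations are generated by two independent telegraph (random-telegraph-
noise) processes — one per transition — each hopping by the extension quantum
released per opening event (``plectoneme_slope`` × turns quantum), plus a
mean-reverting (AR(1)/Ornstein–Uhlenbeck) bead-relaxation term and white
tracking noise. The long-window variance is therefore

  sigma² = s1(1-s1)·dL1² + s2(1-s2)·dL2² + sigma_bead² + sigma_track²,

maximal at occupancy 1/2, i.e. exactly at the characteristic forces — the
double-peak fingerprint the analysis modules look for.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .constants import HELICAL_REPEAT_BP, TEMPERATURE_K, PNNM_TO_KCAL_PER_MOL
from .wlc import wlc_extension

__all__ = [
    "TetherConfig",
    "SimParams",
    "Trace",
    "ForceRamp",
    "DEFAULT_P_FOLD",
    "default_force_grid",
    "effective_p_fold",
    "state_occupancies",
    "extension_levels",
    "mean_extension",
    "mixing_variance",
    "simulate_trace",
    "simulate_ramp",
    "simulate_ensemble",
    "programmed_g4_stabilization",
    "calibrate_gain",
]

#: Per-ramp probability that the G4 pathway is available, by (construct, ion).
#: Calibrated to the measured double-peak percentages at n_t = -40.
DEFAULT_P_FOLD: dict[tuple[str, str], float] = {
    ("wt", "KCl"): 0.35,
    ("wt", "NaCl"): 0.18,
    ("wt", "LiCl"): 0.11,
    ("mut", "KCl"): 0.12,
}

#: Base hop relaxation rate (1/s) at hop_rate_scale = 1. Correlation time
#: 50 ms, so a 3–4 s window captures >95% of the asymptotic variance.
_BASE_HOP_RATE = 20.0

# Occlusion shape constants: the double-peak probability peaks at an
# intermediate |n_t| (~30 turns opens ~ the promoter length; far larger
# |n_t| buries the region in plectonemes). Normalised to 1 at the
# reference condition n_t = -40 where p_fold is calibrated.
_OCCLUSION_PEAK_TURNS = 30.0
_OCCLUSION_SHAPE = 3.0
_OCCLUSION_REF_TURNS = 40.0


@dataclass(frozen=True)
class TetherConfig:
    """Construct and buffer description of the simulated tether."""

    construct: str = "wt"
    ion: str = "KCl"
    n_basepairs: int = 6680
    contour_length: float = 2000.0
    persistence_length: float = 46.0
    g4_region_bp: int = 72
    n_g4: int = 3
    helical_repeat: float = HELICAL_REPEAT_BP
    p_fold: float | None = None
    temperature: float = TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.construct not in ("wt", "mut"):
            raise ValueError("construct must be 'wt' or 'mut'")
        if self.ion not in ("KCl", "NaCl", "LiCl"):
            raise ValueError("ion must be KCl, NaCl or LiCl")
        if self.contour_length <= 0 or self.persistence_length <= 0:
            raise ValueError("contour and persistence length must be positive")
        if not 0 <= self.g4_region_bp < self.n_basepairs:
            raise ValueError("g4_region_bp must be < n_basepairs")
        if self.p_fold is None:
            object.__setattr__(
                self, "p_fold",
                DEFAULT_P_FOLD.get((self.construct, self.ion), 0.10))
        if not 0.0 <= self.p_fold <= 1.0:
            raise ValueError("p_fold must be a probability")


@dataclass(frozen=True)
class SimParams:
    """Kinetic and noise parameters of the trace generator.

    ``turns_per_g4_event`` is the torsion absorbed when the whole 72 bp
    promoter region opens (72/10.4 ≈ 6.9 turns); ``turns_per_hop`` is the
    quantum of turns exchanged per plectoneme<->bubble hopping event at the
    main transition, which sets the fluctuation amplitude there.
    """

    F_C1: float = 0.37
    F_C2: float = 0.69
    turns_per_g4_event: float = 72 / HELICAL_REPEAT_BP
    plectoneme_slope: float = 55.0
    transition_width: float = 0.04
    hop_rate_scale: float = 1.0
    relax_time: float = 0.05
    tracking_noise_sd: float = 10.0
    bead_noise_sd: float = 15.0
    sample_rate: float = 300.0
    dwell: float = 5.0
    turns_per_hop: float = 72 / HELICAL_REPEAT_BP
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.F_C1 < self.F_C2:
            raise ValueError("F_C1 must be below F_C2")
        if self.transition_width <= 0:
            raise ValueError("transition_width must be positive")
        if self.dwell * self.sample_rate < 2:
            raise ValueError("dwell * sample_rate must be >= 2")
        for name in ("plectoneme_slope", "hop_rate_scale", "relax_time",
                     "tracking_noise_sd", "bead_noise_sd", "sample_rate",
                     "dwell", "turns_per_g4_event", "turns_per_hop"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")


@dataclass
class Trace:
    """Extension time series at one (force, turns) set-point."""

    force: float
    turns: int
    time: np.ndarray
    extension: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.shape != self.extension.shape:
            raise ValueError("time and extension must have equal length")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sample_rate,
                                                  rtol=1e-6, atol=1e-9):
                raise ValueError("time must increase uniformly at 1/sample_rate")
        if not np.all(np.isfinite(self.extension)):
            raise ValueError("extension must be finite")

    @property
    def duration(self) -> float:
        return self.time.size / self.sample_rate


@dataclass
class ForceRamp:
    """Ordered traces over a strictly increasing force grid at fixed turns."""

    traces: list[Trace]
    force_grid: np.ndarray
    turns: int
    g4_available: bool | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.force_grid = np.asarray(self.force_grid, dtype=float)
        if self.force_grid.size == 0:
            raise ValueError("force grid must not be empty")
        if np.any(np.diff(self.force_grid) <= 0):
            raise ValueError("force grid must be strictly increasing")
        if len(self.traces) != self.force_grid.size:
            raise ValueError("one trace per grid force required")
        if any(t.turns != self.turns for t in self.traces):
            raise ValueError("all traces of a ramp must share turns")


def default_force_grid(f_min: float = 0.05, f_max: float = 3.0,
                       step: float = 0.01) -> np.ndarray:
    """The standard acquisition grid: 0.05–3.0 pN in 0.01 pN steps."""
    n = int(round((f_max - f_min) / step)) + 1
    return np.linspace(f_min, f_max, n)


def effective_p_fold(n_t: int, cfg: TetherConfig) -> float:
    """Per-ramp G4-availability probability at imposed turns ``n_t``.

    ``cfg.p_fold`` applies at the reference condition n_t = -40; away from
    it a phenomenological occlusion factor (gamma-shaped in |n_t|, peaked
    near -30 turns) reduces availability: too little underwinding rarely
    opens the promoter, too much buries it in plectonemes. Positive or zero
    turns never open the duplex, so the probability is 0.
    """
    if n_t >= 0:
        return 0.0
    a = _OCCLUSION_SHAPE

    def shape(n: float) -> float:
        r = n / _OCCLUSION_PEAK_TURNS
        return r ** a * np.exp(a * (1.0 - r))

    p = cfg.p_fold * shape(abs(n_t)) / shape(_OCCLUSION_REF_TURNS)
    return float(min(1.0, p))


def _logistics(F, prm: SimParams):
    """Sequential transition weights s1 (P->G) and s2 (->D) at force F."""
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    w = prm.transition_width
    s1 = 1.0 / (1.0 + np.exp(-(F - prm.F_C1) / w))
    s2 = 1.0 / (1.0 + np.exp(-(F - prm.F_C2) / w))
    return s1, s2


def state_occupancies(F, n_t: int, cfg: TetherConfig, prm: SimParams,
                      g4_available: bool):
    """Occupancies (p_P, p_G, p_D) of the three torsional states at force F.

    Sequential two-logistic model: with the G4 pathway available the tether
    passes P -> G at F_C1 and G -> D at F_C2; otherwise P -> D in a single
    logistic at F_C2. For n_t >= 0 no strand opening occurs and the tether
    stays plectonemic/stretched (p_G = p_D = 0).
    """
    s1, s2 = _logistics(F, prm)
    if n_t >= 0:
        z = np.zeros_like(s1)
        return np.ones_like(s1), z, z
    if g4_available:
        p_P = 1.0 - s1
        p_G = s1 * (1.0 - s2)
        p_D = s1 * s2
    else:
        p_P = 1.0 - s2
        p_G = np.zeros_like(s2)
        p_D = s2
    return p_P, p_G, p_D


def extension_levels(F, n_t: int, cfg: TetherConfig, prm: SimParams):
    """Mean extension (nm) of the pure P, G and D states at force F.

    D is the WLC extension; P is shortened by ``plectoneme_slope`` nm per
    imposed turn (floored at zero, the collapsed state); G recovers the
    extension of the turns absorbed by one G4-region opening event.
    """
    F = np.asarray(F, dtype=float)
    Le_D = np.asarray(wlc_extension(F, cfg.contour_length,
                                    cfg.persistence_length, cfg.temperature))
    Le_P = np.maximum(0.0, Le_D - prm.plectoneme_slope * abs(n_t))
    Le_G = Le_P + prm.plectoneme_slope * prm.turns_per_g4_event
    return Le_P, Le_G, Le_D


def mean_extension(F, n_t: int, cfg: TetherConfig, prm: SimParams,
                   g4_available: bool):
    """Occupancy-weighted mean extension (nm) at force F."""
    p_P, p_G, p_D = state_occupancies(F, n_t, cfg, prm, g4_available)
    Le_P, Le_G, Le_D = extension_levels(F, n_t, cfg, prm)
    out = p_P * Le_P + p_G * Le_G + p_D * Le_D
    return out if np.asarray(out).ndim else float(out)


def _hop_amplitudes(n_t: int, prm: SimParams, g4_available: bool):
    """Telegraph amplitudes (nm) for the two transitions."""
    if n_t >= 0:
        return 0.0, 0.0
    amp2 = prm.plectoneme_slope * prm.turns_per_hop
    amp1 = prm.plectoneme_slope * prm.turns_per_g4_event if g4_available else 0.0
    return amp1, amp2


def mixing_variance(F, n_t: int, cfg: TetherConfig, prm: SimParams,
                    g4_available: bool, include_noise: bool = True):
    """Asymptotic (long-window) extension variance (nm²) at force F.

    Sum of the two telegraph mixing terms s(1-s)·dL² plus, optionally, the
    bead-relaxation and tracking noise floor.
    """
    s1, s2 = _logistics(F, prm)
    amp1, amp2 = _hop_amplitudes(n_t, prm, g4_available)
    var = s1 * (1.0 - s1) * amp1 ** 2 + s2 * (1.0 - s2) * amp2 ** 2
    if include_noise:
        var = var + prm.bead_noise_sd ** 2 + prm.tracking_noise_sd ** 2
    return var if np.asarray(var).ndim else float(var)


def _simulate_telegraphs(s, k_relax: float, dt: float, n_steps: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Simulate independent two-state telegraphs, one per row.

    ``s`` is the stationary up-state probability per row; the relaxation
    rate (k_up + k_down) is ``k_relax`` everywhere, giving a correlation
    time 1/k_relax independent of occupancy. Returns a (len(s), n_steps)
    float array of 0/1 states; chains start in their stationary law.
    """
    s = np.asarray(s, dtype=float)
    p_up = np.clip(k_relax * s * dt, 0.0, 1.0)        # 0 -> 1 per step
    p_down = np.clip(k_relax * (1.0 - s) * dt, 0.0, 1.0)  # 1 -> 0 per step
    b = rng.random(s.shape) < s
    u = rng.random((s.size, n_steps))
    out = np.empty((s.size, n_steps))
    for t in range(n_steps):
        ut = u[:, t]
        b = np.where(b, ut >= p_down, ut < p_up)
        out[:, t] = b
    return out


def _simulate_extensions(forces: np.ndarray, n_t: int, cfg: TetherConfig,
                         prm: SimParams, g4_available: bool,
                         rng: np.random.Generator) -> np.ndarray:
    """Extension time series for every force in ``forces`` (rows)."""
    forces = np.asarray(forces, dtype=float)
    n_steps = int(round(prm.dwell * prm.sample_rate))
    dt = 1.0 / prm.sample_rate
    s1, s2 = _logistics(forces, prm)
    amp1, amp2 = _hop_amplitudes(n_t, prm, g4_available)
    mean = np.asarray(mean_extension(forces, n_t, cfg, prm, g4_available))

    k_relax = _BASE_HOP_RATE * prm.hop_rate_scale
    x = np.broadcast_to(mean[:, None], (forces.size, n_steps)).copy()
    if amp1 > 0:
        b1 = _simulate_telegraphs(s1, k_relax, dt, n_steps, rng)
        x += amp1 * (b1 - s1[:, None])
    if amp2 > 0:
        b2 = _simulate_telegraphs(s2, k_relax, dt, n_steps, rng)
        x += amp2 * (b2 - s2[:, None])

    # bead relaxation: stationary AR(1) with time constant relax_time
    if prm.bead_noise_sd > 0 and prm.relax_time > 0:
        a = np.exp(-dt / prm.relax_time)
        c = prm.bead_noise_sd * np.sqrt(1.0 - a * a)
        eps = rng.standard_normal((forces.size, n_steps))
        x0 = prm.bead_noise_sd * rng.standard_normal(forces.size)
        ou, _ = lfilter([c], [1.0, -a], eps, axis=1, zi=(a * x0)[:, None])
        x += ou
    if prm.tracking_noise_sd > 0:
        x += prm.tracking_noise_sd * rng.standard_normal((forces.size, n_steps))
    return x


def _seed_token(seed):
    """Compact, single-line representation of a seed for metadata headers."""
    if isinstance(seed, (int, np.integer)) or seed is None:
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return (f"entropy={seed.entropy};"
                f"spawn_key={','.join(map(str, seed.spawn_key))}")
    return " ".join(str(seed).split())


def _trace_meta(cfg: TetherConfig, prm: SimParams, g4_available: bool,
                seed) -> dict:
    seed = _seed_token(seed)
    return {
        "construct": cfg.construct,
        "ion": cfg.ion,
        "g4_available": bool(g4_available),
        "seed": seed,
        "config": dataclasses.asdict(cfg),
        "params": dataclasses.asdict(prm),
    }


def simulate_trace(F: float, n_t: int, cfg: TetherConfig, prm: SimParams,
                   g4_available: bool, seed) -> Trace:
    """Simulate one extension trace at fixed force and turns.

    ``seed`` may be an int or a numpy SeedSequence/Generator; the same seed
    reproduces the trace bit for bit.
    """
    if not np.isfinite(F) or F < 0:
        raise ValueError("force must be finite and non-negative")
    rng = np.random.default_rng(seed)
    x = _simulate_extensions(np.array([F]), n_t, cfg, prm, g4_available, rng)[0]
    time = np.arange(x.size) / prm.sample_rate
    return Trace(force=float(F), turns=int(n_t), time=time, extension=x,
                 sample_rate=prm.sample_rate,
                 meta=_trace_meta(cfg, prm, g4_available, seed))


def simulate_ramp(n_t: int, cfg: TetherConfig, prm: SimParams,
                  g4_available: bool, force_grid=None, seed=0) -> ForceRamp:
    """Simulate a force ramp: one trace per grid force, shared seed stream."""
    grid = default_force_grid() if force_grid is None else \
        np.asarray(force_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("force grid must not be empty")
    rng = np.random.default_rng(seed)
    x = _simulate_extensions(grid, n_t, cfg, prm, g4_available, rng)
    time = np.arange(x.shape[1]) / prm.sample_rate
    meta = _trace_meta(cfg, prm, g4_available, seed)
    traces = [
        Trace(force=float(f), turns=int(n_t), time=time, extension=x[i],
              sample_rate=prm.sample_rate, meta=meta)
        for i, f in enumerate(grid)
    ]
    return ForceRamp(traces=traces, force_grid=grid, turns=int(n_t),
                     g4_available=bool(g4_available), meta=meta)


def simulate_ensemble(n_ramps: int, n_t: int, cfg: TetherConfig,
                      prm: SimParams, seed=0, force_grid=None,
                      p_fold: float | None = None) -> list[ForceRamp]:
    """Simulate an ensemble of ramps with Bernoulli G4 availability.

    Each ramp's ``g4_available`` flag is drawn with probability
    ``effective_p_fold(n_t, cfg)`` (or an explicit ``p_fold`` override) and
    recorded on the ramp as ground truth for classifier validation.
    """
    if n_ramps < 1:
        raise ValueError("n_ramps must be >= 1")
    if p_fold is None:
        p_fold = effective_p_fold(n_t, cfg)
    ss = np.random.SeedSequence(seed)
    flag_rng = np.random.default_rng(ss.spawn(1)[0])
    children = ss.spawn(n_ramps + 1)[1:]
    flags = flag_rng.random(n_ramps) < p_fold
    return [
        simulate_ramp(n_t, cfg, prm, bool(flags[i]), force_grid, children[i])
        for i in range(n_ramps)
    ]


def programmed_g4_stabilization(prm: SimParams) -> float:
    """Net stabilization energy (kcal/mol) the generator programs into the
    G4 pathway: the extension quantum released by one G4-region opening,
    held over the force gap between the two transitions,
    plectoneme_slope · turns_per_g4_event · (F_C2 − F_C1).
    """
    pnnm = prm.plectoneme_slope * prm.turns_per_g4_event * (prm.F_C2 - prm.F_C1)
    return pnnm * PNNM_TO_KCAL_PER_MOL


def calibrate_gain(prm: SimParams, target_kcal_mol: float) -> SimParams:
    """Return params whose programmed G4 stabilization equals the target.

    Solves for ``plectoneme_slope`` in the closed form of
    :func:`programmed_g4_stabilization`; all other parameters unchanged.
    """
    if target_kcal_mol <= 0:
        raise ValueError("target energy must be positive")
    slope = target_kcal_mol / (
        PNNM_TO_KCAL_PER_MOL * prm.turns_per_g4_event * (prm.F_C2 - prm.F_C1))
    return replace(prm, plectoneme_slope=slope)
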