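"""Energy bookkeeping of duplex opening versus G4-assisted opening.

Relaxing one negative turn by opening the double strand costs

    alpha = pi * sqrt(8 * B * F_C),        B = L_p * k_B * T,

so the ratio of the opening energies along the G4-assisted path (transition
at F_C1) and the direct path (F_C2) is sqrt(F_C1 / F_C2) — the bending
constant cancels. Applied to the literature cost of opening the whole
G4-forming region (~120 kcal/mol), the ratio gives the cost with G4 folding
and the net gain. Independently, the work difference between the mean
force–extension curves of the two cohorts is the area between them,
integral of (Le_hi − Le_lo) dF, converted to kcal/mol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import (HELICAL_REPEAT_BP, TEMPERATURE_K,
                        PNNM_TO_KCAL_PER_MOL, kbt, pNnm_to_kcalmol)
from .wlc import MeanCurve

__all__ = [
    "EnergyLedger",
    "SupercoilState",
    "alpha_per_turn",
    "energy_ratio",
    "g4_ledger",
    "work_area",
    "supercoil_density",
    "pNnm_to_kcalmol",
    "build_ledger",
]


@dataclass(frozen=True)
class EnergyLedger:
    """Full energy ledger of the duplex vs G4-path comparison.

    Energies are kcal/mol except the alpha values, which are carried in
    both pN·nm and kcal/mol per relaxed turn. Display rounding is applied
    only when formatting; full precision is retained here.
    """

    B: float                      # bending constant, pN·nm²
    alpha_C1_pNnm: float
    alpha_C2_pNnm: float
    alpha_C1_kcal: float
    alpha_C2_kcal: float
    ratio: float
    E_duplex: float
    E_g4_path: float
    net_gain: float
    work_area: float | None = None
    per_g4_gain_reference: float = 10.0
    n_g4: int = 3

    def __post_init__(self) -> None:
        for name in ("B", "alpha_C1_pNnm", "alpha_C2_pNnm", "E_duplex",
                     "E_g4_path", "net_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.ratio <= 1.0:
            raise ValueError("ratio must be in (0, 1] for F_C1 <= F_C2")

    @property
    def expected_gain_reference(self) -> float:
        """n_g4 × the per-G4 literature gain, kcal/mol."""
        return self.n_g4 * self.per_g4_gain_reference

    def format(self) -> str:
        """Human-readable ledger, values rounded to 2 significant figures."""
        def r2(x: float) -> float:
            if x == 0:
                return 0.0
            return float(np.round(x, 1 - int(np.floor(np.log10(abs(x))))))

        lines = [
            "Energy ledger (duplex opening vs G4-assisted opening)",
            f"  bending constant B          : {r2(self.B)} pN nm^2",
            f"  alpha(F_C1) per turn        : {r2(self.alpha_C1_pNnm)} pN nm "
            f"= {r2(self.alpha_C1_kcal)} kcal/mol",
            f"  alpha(F_C2) per turn        : {r2(self.alpha_C2_pNnm)} pN nm "
            f"= {r2(self.alpha_C2_kcal)} kcal/mol",
            f"  transition-energy ratio     : {self.ratio:.2f}",
            f"  duplex opening cost         : {r2(self.E_duplex)} kcal/mol",
            f"  G4-path opening cost        : {r2(self.E_g4_path)} kcal/mol",
            f"  net gain from G4 folding    : {r2(self.net_gain)} kcal/mol",
            f"  reference {self.n_g4} x "
            f"{r2(self.per_g4_gain_reference)} kcal/mol    : "
            f"{r2(self.expected_gain_reference)} kcal/mol",
        ]
        if self.work_area is not None:
            lines.append(
                f"  work area between cohorts   : {r2(self.work_area)} kcal/mol")
        return "\n".join(lines)


@dataclass(frozen=True)
class SupercoilState:
    """Imposed turns and the resulting supercoiling density."""

    n_t: int
    N_b: int
    helical_repeat: float = HELICAL_REPEAT_BP

    @property
    def sigma(self) -> float:
        return supercoil_density(self.n_t, self.N_b, self.helical_repeat)


def alpha_per_turn(F_C: float, Lp: float = 46.0,
                   temperature: float = TEMPERATURE_K) -> float:
    """Energy cost (pN·nm) of relaxing one turn by strand opening at F_C.

    alpha = pi * sqrt(8 * B * F_C) with B = Lp * k_B * T. Convert with
    :func:`pNnm_to_kcalmol` for kcal/mol per turn.
    """
    if F_C < 0 or Lp <= 0:
        raise ValueError("F_C must be >= 0 and Lp > 0")
    B = Lp * kbt(temperature)
    return float(np.pi * np.sqrt(8.0 * B * F_C))


def energy_ratio(F_C1: float, F_C2: float) -> float:
    """Ratio of the two transition energies, sqrt(F_C1 / F_C2).

    Identically equals alpha_per_turn(F_C1)/alpha_per_turn(F_C2): the
    bending constant cancels.
    """
    if F_C1 <= 0 or F_C2 <= 0:
        raise ValueError("characteristic forces must be positive")
    return float(np.sqrt(F_C1 / F_C2))


def g4_ledger(E_duplex: float, ratio: float):
    """Opening cost along the G4 path and the net gain, kcal/mol.

    Returns ``(E_g4_path, net_gain)`` = (ratio·E_duplex, E_duplex·(1−ratio))
    at full precision; rounding is display-only.
    """
    if E_duplex <= 0:
        raise ValueError("E_duplex must be positive")
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    E_g4 = ratio * E_duplex
    return E_g4, E_duplex - E_g4


def work_area(curve_hi: MeanCurve, curve_lo: MeanCurve, F_range=None,
              endpoint_rtol: float = 0.1) -> float:
    """Area between two mean force–extension curves, in kcal/mol.

    Trapezoidal integral of (Le_hi − Le_lo) dF over the overlapping force
    range (equivalent to the work difference ∫F dLe when the curves
    coincide at the endpoints). Positive when ``curve_hi`` lies above
    ``curve_lo``. Warns if the endpoint gap exceeds ``endpoint_rtol`` of
    the maximum separation.
    """
    lo = max(curve_hi.force[0], curve_lo.force[0])
    hi = min(curve_hi.force[-1], curve_lo.force[-1])
    if F_range is not None:
        lo, hi = max(lo, F_range[0]), min(hi, F_range[1])
    if hi <= lo:
        raise ValueError("curves have no overlapping force range")
    grid = np.union1d(
        curve_hi.force[(curve_hi.force >= lo) & (curve_hi.force <= hi)],
        curve_lo.force[(curve_lo.force >= lo) & (curve_lo.force <= hi)])
    ext_hi = np.interp(grid, curve_hi.force, curve_hi.extension_mean)
    ext_lo = np.interp(grid, curve_lo.force, curve_lo.extension_mean)
    diff = ext_hi - ext_lo
    peak = float(np.max(np.abs(diff))) if diff.size else 0.0
    if peak > 0 and max(abs(diff[0]), abs(diff[-1])) > endpoint_rtol * peak:
        warnings.warn("curves do not coincide at the integration endpoints; "
                      "the area is not a pure work difference", stacklevel=2)
    area_pNnm = float(np.trapezoid(diff, grid))
    return pNnm_to_kcalmol(area_pNnm)


def supercoil_density(n_t: float, N_b: float,
                      helical_repeat: float = HELICAL_REPEAT_BP) -> float:
    """Supercoiling density sigma = n_t / (N_b / helical_repeat)."""
    if N_b <= 0:
        raise ValueError("N_b must be positive")
    return float(n_t * helical_repeat / N_b)


def build_ledger(F_C1: float = 0.37, F_C2: float = 0.69, Lp: float = 46.0,
                 E_duplex: float = 120.0, temperature: float = TEMPERATURE_K,
                 work_area_kcal: float | None = None,
                 per_g4_gain_reference: float = 10.0,
                 n_g4: int = 3) -> EnergyLedger:
    """Assemble the full energy ledger from the two characteristic forces."""
    a1 = alpha_per_turn(F_C1, Lp, temperature)
    a2 = alpha_per_turn(F_C2, Lp, temperature)
    ratio = energy_ratio(F_C1, F_C2)
    E_g4, gain = g4_ledger(E_duplex, ratio)
    return EnergyLedger(
        B=Lp * kbt(temperature),
        alpha_C1_pNnm=a1, alpha_C2_pNnm=a2,
        alpha_C1_kcal=pNnm_to_kcalmol(a1), alpha_C2_kcal=pNnm_to_kcalmol(a2),
        ratio=ratio, E_duplex=E_duplex, E_g4_path=E_g4, net_gain=gain,
        work_area=work_area_kcal,
        per_g4_gain_reference=per_g4_gain_reference, n_g4=n_g4)
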