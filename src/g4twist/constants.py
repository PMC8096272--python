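"""Physical constants and unit conversions used throughout the package.

Forces are in pN, lengths in nm, energies in pN·nm unless a function says
otherwise; kcal/mol is used only for reporting.
"""

#: Thermal energy k_B·T at 298 K, in pN·nm (fixed; the instrument runs at
#: room temperature and the analysis is insensitive to ±2 K).
KBT_PN_NM: float = 4.11

#: Reference temperature, K.
TEMPERATURE_K: float = 298.0

#: 1 pN·nm = 1e-21 J; × Avogadro / 4184 J·kcal⁻¹ = 0.14393 kcal/mol.
PNNM_TO_KCAL_PER_MOL: float = 0.14393

#: B-DNA helical repeat, bp per turn.
HELICAL_REPEAT_BP: float = 10.4


def kbt(temperature: float = TEMPERATURE_K) -> float:
    """Thermal energy in pN·nm at ``temperature`` (scaled from 4.11 at 298 K)."""
    return KBT_PN_NM * (temperature / TEMPERATURE_K)


def pNnm_to_kcalmol(x: float) -> float:
    """Convert an energy from pN·nm to kcal/mol."""
    return x * PNNM_TO_KCAL_PER_MOL
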