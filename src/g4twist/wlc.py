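"""Worm-like-chain elasticity: force–extension model and parameter fitting.

The entropic elasticity of torsionally relaxed double-stranded DNA is
described by the Marko–Siggia interpolation of the worm-like chain (WLC),

    F(x) = (k_B T / L_p) · [ 1/(4 (1 − x/L_0)²) − 1/4 + x/L_0 ],

with contour length ``L_0`` and persistence length ``L_p``. Below ~10 pN the
interpolation is accurate to a few percent and the enthalpic stretch modulus
is irrelevant, which is the regime of these experiments (< 3 pN).

Fitting is done in the extension-as-function-of-force direction (the way the
data are plotted), optionally weighted by the per-point standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import lmfit
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import TEMPERATURE_K, kbt

__all__ = [
    "WLCParams",
    "MeanCurve",
    "wlc_force",
    "wlc_extension",
    "WormLikeChainFit",
    "fit_wlc",
]


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain parameters (nm) with fit uncertainties."""

    L0: float
    Lp: float
    temperature: float = TEMPERATURE_K
    L0_err: float = 0.0
    Lp_err: float = 0.0

    def __post_init__(self) -> None:
        if not (self.L0 > 0 and self.Lp > 0):
            raise ValueError("contour and persistence length must be positive")
        if self.L0_err < 0 or self.Lp_err < 0:
            raise ValueError("uncertainties must be non-negative")


@dataclass
class MeanCurve:
    """A mean force–extension curve: per-force mean, SD and sample count."""

    force: np.ndarray
    extension_mean: np.ndarray
    extension_sd: np.ndarray | None = None
    n_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.extension_mean = np.asarray(self.extension_mean, dtype=float)
        if self.force.shape != self.extension_mean.shape:
            raise ValueError("force and extension arrays must have equal length")
        if np.any(np.diff(self.force) <= 0):
            raise ValueError("force grid must be strictly increasing")
        if self.extension_sd is not None:
            self.extension_sd = np.asarray(self.extension_sd, dtype=float)
            if self.extension_sd.shape != self.force.shape:
                raise ValueError("extension_sd length mismatch")
            if np.any(self.extension_sd < 0):
                raise ValueError("extension_sd must be non-negative")


def wlc_force(x, L0: float, Lp: float, temperature: float = TEMPERATURE_K):
    """Marko–Siggia WLC force (pN) at extension ``x`` (nm).

    Raises for extensions at or beyond the contour length, where the
    interpolation diverges.
    """
    x = np.asarray(x, dtype=float)
    if L0 <= 0 or Lp <= 0:
        raise ValueError("L0 and Lp must be positive")
    if np.any(x < 0) or np.any(x >= L0):
        raise ValueError("extension must satisfy 0 <= x < L0")
    u = x / L0
    f = 0.25 / (1.0 - u) ** 2 - 0.25 + u
    out = (kbt(temperature) / Lp) * f
    return out if out.ndim else float(out)


def wlc_extension(F, L0: float, Lp: float, temperature: float = TEMPERATURE_K,
                  rtol: float = 1e-12):
    """Numerically invert the Marko–Siggia relation: extension (nm) at force F (pN).

    Vectorised safeguarded Newton iteration on the reduced extension u = x/L0;
    the residual force is matched to relative tolerance ``rtol`` (default well
    below 1e-9). Returns 0 at F = 0.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    f = F * Lp / kbt(temperature)  # dimensionless force

    # seeds from the low- and high-force limits of the interpolation
    with np.errstate(divide="ignore"):
        hi = 1.0 - 0.5 / np.sqrt(np.maximum(f, 1e-300))
    u = np.where(f < 1.0, 2.0 * f / 3.0, hi)
    u = np.clip(u, 0.0, 1.0 - 1e-9)

    for _ in range(100):
        g = 0.25 / (1.0 - u) ** 2 - 0.25 + u - f
        dg = 0.5 / (1.0 - u) ** 3 + 1.0
        step = g / dg
        u_new = np.clip(u - step, 0.0, 1.0 - 1e-15)
        u = u_new
        if np.all(np.abs(g) <= rtol * np.maximum(f, 1e-30) + 1e-15):
            break
    x = u * L0
    return x if x.ndim else float(x)


class WormLikeChainFit(BaseEstimator, RegressorMixin):
    """Least-squares WLC fit of extension versus force.

    Parameters
    ----------
    temperature : float
        Temperature in K (sets k_B T).
    weighted : bool
        Weight residuals by 1/sd where a per-point SD is supplied.

    Attributes (after ``fit``)
    --------------------------
    contour_length_, persistence_length_ : fitted L0, Lp in nm.
    contour_length_err_, persistence_length_err_ : standard errors from the
        fit covariance.
    success_ : bool, convergence status; ``fit`` raises on failure rather
        than returning silent defaults.
    """

    def __init__(self, temperature: float = TEMPERATURE_K, weighted: bool = True):
        self.temperature = temperature
        self.weighted = weighted

    def fit(self, force, extension, extension_sd=None):
        force = np.asarray(force, dtype=float).ravel()
        extension = np.asarray(extension, dtype=float).ravel()
        if force.size != extension.size:
            raise ValueError("force and extension must have equal length")
        if force.size < 6:
            raise ValueError("need at least 6 points spanning the force range")

        order = np.argsort(force)
        force, extension = force[order], extension[order]
        weights = None
        if extension_sd is not None and self.weighted:
            sd = np.asarray(extension_sd, dtype=float).ravel()[order]
            if np.all(sd > 0):
                weights = 1.0 / sd

        xmax = float(np.max(extension))
        params = lmfit.Parameters()
        params.add("L0", value=max(xmax * 1.05, 1.0), min=1e-6, max=2.0 * max(xmax, 1.0))
        params.add("Lp", value=50.0, min=1.0, max=200.0)

        def model(p):
            return wlc_extension(force, p["L0"].value, p["Lp"].value, self.temperature)

        def residual(p):
            r = model(p) - extension
            return r * weights if weights is not None else r

        result = lmfit.minimize(residual, params, method="leastsq")
        if not result.success:
            raise RuntimeError(f"WLC fit did not converge: {result.message}")
        self.result_ = result
        self.contour_length_ = float(result.params["L0"].value)
        self.persistence_length_ = float(result.params["Lp"].value)
        self.contour_length_err_ = float(result.params["L0"].stderr or 0.0)
        self.persistence_length_err_ = float(result.params["Lp"].stderr or 0.0)
        self.success_ = bool(result.success)
        return self

    def predict(self, force):
        return wlc_extension(np.asarray(force, dtype=float),
                             self.contour_length_, self.persistence_length_,
                             self.temperature)

    @property
    def params_(self) -> WLCParams:
        return WLCParams(self.contour_length_, self.persistence_length_,
                         self.temperature, self.contour_length_err_,
                         self.persistence_length_err_)


def fit_wlc(curve: MeanCurve, weighted: bool = True,
            temperature: float = TEMPERATURE_K) -> WLCParams:
    """Fit the WLC model to a mean force–extension curve.

    Weighted least squares with weights 1/sd² where SDs are available and
    positive, otherwise unweighted.
    """
    est = WormLikeChainFit(temperature=temperature, weighted=weighted)
    est.fit(curve.force, curve.extension_mean, curve.extension_sd)
    return est.params_
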