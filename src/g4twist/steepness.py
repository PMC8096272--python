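"""Steepness of supercoiled force–extension curves and its statistics.

Under fixed negative turns the mean extension rises sigmoidally with force;
the curve is summarised by the phenomenological logistic

    L_e(F) = a + b / (1 + exp((F − F1) / S0)),

where F1 is the symmetric point and S0 (pN) the steepness parameter —
larger S0, shallower transition. Note that with the exponent written this
way the curve increases with force when b < 0; the fit keeps the form as
written and reports the sign of b rather than silently flipping it.

Per-ramp S0 values are compared between cohorts with the Wilcoxon rank-sum
test and their distribution is decomposed into one or two Gaussian
components by maximum-likelihood EM; the relative component areas are the
mixture weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit
from scipy import stats
from sklearn.base import BaseEstimator, DensityMixin, RegressorMixin
from sklearn.mixture import GaussianMixture

from .wlc import MeanCurve

__all__ = [
    "LogisticParams",
    "MixtureFit",
    "logistic_extension",
    "LogisticCurveFit",
    "fit_logistic",
    "SteepnessMixture",
    "fit_s0_mixture",
    "select_mixture",
    "compare_s0_distributions",
]


@dataclass(frozen=True)
class LogisticParams:
    """Fitted logistic parameters with standard errors."""

    a: float
    b: float
    F1: float
    S0: float
    a_err: float = 0.0
    b_err: float = 0.0
    F1_err: float = 0.0
    S0_err: float = 0.0

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


@dataclass(frozen=True)
class MixtureFit:
    """Gaussian mixture decomposition of an S0 sample.

    ``weights`` are the relative areas; for k = 2 the components are
    ordered by increasing mean. ``bic`` is the model-selection score
    (lower is better).
    """

    k: int
    weights: tuple
    means: tuple
    sds: tuple
    log_likelihood: float
    bic: float

    def __post_init__(self) -> None:
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if abs(sum(self.weights) - 1.0) > 1e-8 or any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative and sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("SDs must be positive")
        if self.k == 2 and not self.means[0] <= self.means[1]:
            raise ValueError("components must be ordered by mean")

    @property
    def relative_areas(self) -> tuple:
        return self.weights


def logistic_extension(F, a: float, b: float, F1: float, S0: float):
    """The logistic force–extension form, exponent (F − F1)/S0 as written."""
    F = np.asarray(F, dtype=float)
    out = a + b / (1.0 + np.exp((F - F1) / S0))
    return out if out.ndim else float(out)


class LogisticCurveFit(BaseEstimator, RegressorMixin):
    """Least-squares logistic fit of a mean force–extension curve.

    Attributes after ``fit``: ``a_``, ``b_``, ``F1_``, ``S0_`` with
    ``*_err_`` standard errors and ``success_``. Non-convergence raises.
    """

    def __init__(self, weighted: bool = False):
        self.weighted = weighted

    def fit(self, force, extension, extension_sd=None):
        force = np.asarray(force, dtype=float).ravel()
        extension = np.asarray(extension, dtype=float).ravel()
        if force.size != extension.size:
            raise ValueError("force and extension must have equal length")
        if force.size < 8:
            raise ValueError("need at least 8 points bracketing the transition")
        order = np.argsort(force)
        force, extension = force[order], extension[order]
        weights = None
        if extension_sd is not None and self.weighted:
            sd = np.asarray(extension_sd, dtype=float).ravel()[order]
            if np.all(sd > 0):
                weights = 1.0 / sd

        lo, hi = float(np.min(extension)), float(np.max(extension))
        rng_ext = hi - lo
        # robust initialisation: a = min, b = range, F1 at half range, S0 = 0.5
        half = lo + 0.5 * rng_ext
        F1_0 = float(force[np.argmin(np.abs(extension - half))])
        params = lmfit.Parameters()
        params.add("a", value=lo)
        params.add("b", value=rng_ext if rng_ext > 0 else 1.0)
        params.add("F1", value=F1_0)
        params.add("S0", value=0.5, min=1e-4)

        def residual(p):
            r = logistic_extension(force, p["a"].value, p["b"].value,
                                   p["F1"].value, p["S0"].value) - extension
            return r * weights if weights is not None else r

        result = lmfit.minimize(residual, params, method="leastsq")
        if not result.success:
            raise RuntimeError(f"logistic fit did not converge: {result.message}")
        self.result_ = result
        for name in ("a", "b", "F1", "S0"):
            setattr(self, f"{name}_", float(result.params[name].value))
            setattr(self, f"{name}_err_",
                    float(result.params[name].stderr or 0.0))
        self.success_ = bool(result.success)
        return self

    def predict(self, force):
        return logistic_extension(np.asarray(force, dtype=float),
                                  self.a_, self.b_, self.F1_, self.S0_)

    @property
    def params_(self) -> LogisticParams:
        return LogisticParams(self.a_, self.b_, self.F1_, self.S0_,
                              self.a_err_, self.b_err_, self.F1_err_,
                              self.S0_err_)


def fit_logistic(curve: MeanCurve, weighted: bool = False) -> LogisticParams:
    """Fit the logistic form to a mean force–extension curve."""
    est = LogisticCurveFit(weighted=weighted)
    est.fit(curve.force, curve.extension_mean, curve.extension_sd)
    return est.params_


class SteepnessMixture(BaseEstimator, DensityMixin):
    """One- or two-component Gaussian mixture of S0 samples via EM.

    20 random restarts, best likelihood kept; degenerate (near-zero
    variance) solutions are rejected and refit with a variance floor.
    S0 values enter untransformed.
    """

    def __init__(self, k: int = 2, n_init: int = 20, random_state: int = 0):
        self.k = k
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, samples, y=None):
        samples = np.asarray(samples, dtype=float).ravel()
        if samples.size < 30:
            raise ValueError("need at least 30 samples")
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        X = samples[:, None]
        scale = float(np.var(samples))
        reg = 1e-6 * max(scale, 1e-12)
        for attempt in range(3):
            gm = GaussianMixture(n_components=self.k, n_init=self.n_init,
                                 covariance_type="full", reg_covar=reg,
                                 random_state=self.random_state + attempt)
            gm.fit(X)
            sds = np.sqrt(gm.covariances_.ravel())
            if np.all(sds > 1e-6 * np.sqrt(max(scale, 1e-12))):
                break
            reg *= 100  # degenerate spike: refit with a stronger floor
        order = np.argsort(gm.means_.ravel())
        self.weights_ = tuple(float(w) for w in gm.weights_[order])
        self.means_ = tuple(float(m) for m in gm.means_.ravel()[order])
        self.sds_ = tuple(float(s) for s in sds[order])
        self.log_likelihood_ = float(gm.score(X) * samples.size)
        self.bic_ = float(gm.bic(X))
        self._gm = gm
        return self

    @property
    def fit_(self) -> MixtureFit:
        return MixtureFit(self.k, self.weights_, self.means_, self.sds_,
                          self.log_likelihood_, self.bic_)


def fit_s0_mixture(s0_samples, k: int = 2, n_init: int = 20,
                   random_state: int = 0) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture fit of an S0 sample."""
    est = SteepnessMixture(k=k, n_init=n_init, random_state=random_state)
    est.fit(s0_samples)
    return est.fit_


def select_mixture(s0_samples, n_init: int = 20, random_state: int = 0):
    """Fit both k = 1 and k = 2 and pick by BIC. Returns (best, k1, k2)."""
    one = fit_s0_mixture(s0_samples, k=1, n_init=n_init,
                         random_state=random_state)
    two = fit_s0_mixture(s0_samples, k=2, n_init=n_init,
                         random_state=random_state)
    best = one if one.bic <= two.bic else two
    return best, one, two


def compare_s0_distributions(samples_a, samples_b):
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test between S0 samples.

    Normal approximation with tie correction. Returns ``(statistic, p)``
    where the statistic is the Mann–Whitney U of the first sample.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.size < 10 or b.size < 10:
        raise ValueError("each group needs at least 10 samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return float(res.statistic), float(res.pvalue)
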