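"""Saturating absorbance–concentration calibration and its inverse.

In a dense algal suspension, cells shade one another, so each added cell
raises optical density by less than the last: dA/dc = k·(A_max − A), whose
solution is the saturating law

    A(c) = A_max · (1 − e^(−k·c)),

with A_max the asymptotic absorbance of a fully self-shading suspension and
k the specific light absorption coefficient (per mg d.m./L).  This is the
Box–Lucas form y = a·(1 − e^(−b·x)) and reduces to the Beer–Lambert linear
law A ≈ A_max·k·c when k·c ≪ 1.  Inverting it gives the biomass estimator

    c = ln(1 − A/A_max) / (−k),

whose shipped default constants (A_max = 3.29, k = 0.0022 at 440 nm) apply
to a particular culture and instrument; refit them for any other setup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .corrscan import RegressionError, simple_linreg

__all__ = [
    "CalibrationModel",
    "ModelComparison",
    "saturation_absorbance",
    "estimate_biomass_od440",
    "fit_linear",
    "fit_box_lucas",
    "compare_models",
    "DEFAULT_A_MAX",
    "DEFAULT_K",
    "DEFAULT_WAVELENGTH",
]

#: Default saturating-calibration constants for OD at 440 nm against dry
#: biomass (mg d.m./L).  Culture- and instrument-specific; see fit_box_lucas.
DEFAULT_A_MAX = 3.29
DEFAULT_K = 0.0022
DEFAULT_WAVELENGTH = 440.0


class CalibrationError(ValueError):
    pass


class ConvergenceError(CalibrationError):
    """Nonlinear fit failed to converge within the iteration cap."""


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted absorbance–concentration model at one wavelength.

    ``family`` is 'saturating' (fields ``a_max``, ``k``) or 'linear'
    (fields ``slope``, ``intercept``).  ``r2`` is computed in the original
    response space (1 − SSE/SST) for both families so the two are directly
    comparable.
    """

    family: Literal["linear", "saturating"]
    r2: float
    n: int
    wavelength: float = DEFAULT_WAVELENGTH
    a_max: float | None = None
    k: float | None = None
    slope: float | None = None
    intercept: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if self.family == "saturating":
            if self.a_max is None or self.k is None:
                raise CalibrationError("saturating model needs a_max and k")
            if self.a_max <= 0 or self.k <= 0:
                raise CalibrationError(
                    f"saturating model needs a_max > 0 and k > 0, "
                    f"got a_max={self.a_max}, k={self.k}"
                )
        elif self.family == "linear":
            if self.slope is None or self.intercept is None:
                raise CalibrationError("linear model needs slope and intercept")
        else:
            raise CalibrationError(f"unknown family {self.family!r}")
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise CalibrationError(f"r2 {self.r2} outside [0, 1]")

    def predict(self, c):
        """Absorbance predicted at concentration c."""
        c = np.asarray(c, dtype=float)
        if self.family == "saturating":
            return saturation_absorbance(c, self.a_max, self.k)
        return self.slope * c + self.intercept

    def estimate(self, od):
        """Concentration estimated from absorbance (model inverse)."""
        if self.family == "saturating":
            return estimate_biomass_od440(od, a_max=self.a_max, k=self.k)
        if self.slope == 0:
            raise CalibrationError("flat linear model is not invertible")
        return (np.asarray(od, dtype=float) - self.intercept) / self.slope

    def to_dict(self) -> dict:
        d = {"family": self.family, "r2": self.r2, "n": self.n,
             "wavelength": self.wavelength, "converged": self.converged}
        if self.family == "saturating":
            d.update(a_max=self.a_max, k=self.k)
        else:
            d.update(slope=self.slope, intercept=self.intercept)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**d)


def saturation_absorbance(c, a_max: float = DEFAULT_A_MAX, k: float = DEFAULT_K):
    """A(c) = A_max·(1 − e^(−k·c)): strictly increasing, concave, → A_max.

    The derivative at c = 0 is A_max·k, the slope of the dilute-regime
    Beer–Lambert line.
    """
    if a_max <= 0 or k <= 0:
        raise CalibrationError("a_max and k must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise CalibrationError("concentration must be non-negative")
    out = a_max * (-np.expm1(-k * c))
    return float(out) if out.ndim == 0 else out


def estimate_biomass_od440(od, a_max: float = DEFAULT_A_MAX, k: float = DEFAULT_K):
    """Invert the saturating law: c = ln(1 − OD/A_max)/(−k), mg d.m./L.

    Defined for 0 <= OD < A_max.  An OD at or above A_max is beyond the
    calibrated range — dilute the sample and remeasure.
    """
    if a_max <= 0 or k <= 0:
        raise CalibrationError("a_max and k must be positive")
    od = np.asarray(od, dtype=float)
    if np.any(od < 0):
        raise CalibrationError("optical density must be non-negative")
    if np.any(od >= a_max):
        raise CalibrationError(
            f"OD >= A_max ({a_max}): beyond calibrated range, dilute the sample"
        )
    out = np.log1p(-od / a_max) / (-k)
    return float(out) if out.ndim == 0 else out


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise CalibrationError("x and y must be 1-D and the same length")
    if x.size < 3:
        raise CalibrationError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise CalibrationError("x is constant")
    return x, y


def fit_linear(x, y, wavelength: float = DEFAULT_WAVELENGTH) -> CalibrationModel:
    """Ordinary least-squares line through the calibration points."""
    x, y = _check_xy(x, y)
    try:
        slope, intercept, r2 = simple_linreg(x, y)
    except RegressionError as exc:
        raise CalibrationError(str(exc)) from exc
    return CalibrationModel(
        family="linear", slope=slope, intercept=intercept,
        r2=r2, n=x.size, wavelength=wavelength,
    )


def fit_box_lucas(
    x,
    y,
    wavelength: float = DEFAULT_WAVELENGTH,
    max_iter: int = 500,
    xtol: float = 1e-10,
) -> CalibrationModel:
    """Nonlinear least-squares fit of y = a·(1 − e^(−b·x)).

    Starting values: a₀ = 1.05·max(y) (just above the largest observed
    absorbance), then b₀ from an OLS of the linearisation −ln(1 − y/a₀)
    against x.  Levenberg–Marquardt with relative parameter tolerance
    ``xtol``; exceeding ``max_iter`` function evaluations per parameter is
    a :class:`ConvergenceError`, never a silent result.

    Data confined to the pre-saturation (near-linear) regime leave A_max
    unidentified: the sum of squares has a flat ridge a → ∞, b → 0 with
    a·b fixed at the line's slope, and Levenberg–Marquardt cannot
    terminate on it.  In that case the fit falls back to a bounded 1-D
    search over b with the conditionally optimal a profiled out in closed
    form, which converges to the ridge edge (huge A_max, matching slope)
    and reports an r² equal to the linear fit's to numerical precision.
    """
    x, y = _check_xy(x, y)
    if np.any(y < 0):
        raise CalibrationError("absorbance values must be non-negative")
    if np.ptp(y) == 0:
        raise CalibrationError("y is constant; saturating fit is degenerate")

    a0 = 1.05 * float(np.max(y))
    if a0 <= 0:
        raise CalibrationError("y must contain positive values")
    z = -np.log1p(-np.clip(y / a0, 0.0, 1.0 - 1e-12))
    b0, _, _ = simple_linreg(x, z)
    if b0 <= 0:
        b0 = 1.0 / max(float(np.max(x)), 1e-12)

    def model(c, a, b):
        return a * (-np.expm1(-b * c))

    def _profiled(b: float) -> tuple[float, float]:
        """Conditionally optimal a and the resulting SSE at fixed b."""
        f = -np.expm1(-b * x)
        denom = float(f @ f)
        if denom == 0.0:
            return 0.0, float(y @ y)
        a = float(y @ f) / denom
        resid = y - a * f
        return a, float(resid @ resid)

    a = b = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _, infodict, mesg, ier = curve_fit(
                model, x, y, p0=[a0, b0], full_output=True,
                maxfev=max_iter * 3, xtol=xtol,
            )
        if ier not in (1, 2, 3, 4):
            raise ConvergenceError(f"curve_fit did not converge: {mesg}")
        a, b = float(popt[0]), float(popt[1])
    except (RuntimeError, ConvergenceError):
        # flat-ridge (pre-saturation) fallback: profile a out, search b
        x_max = float(np.max(x))
        b_lo, b_hi = 1e-12 / x_max, 50.0 / x_max
        res = minimize_scalar(
            lambda b_: _profiled(b_)[1], bounds=(b_lo, b_hi),
            method="bounded", options={"xatol": b_lo * 1e-3},
        )
        b = float(res.x)
        a = _profiled(b)[0]
        if not np.isfinite(a) or not np.isfinite(b):
            raise ConvergenceError("profiled fallback failed to converge")
    if a <= 0 or b <= 0:
        raise ConvergenceError(
            f"fit left the admissible region (a={a:.4g}, b={b:.4g})"
        )
    resid = y - model(x, a, b)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst
    return CalibrationModel(
        family="saturating", a_max=a, k=b,
        r2=float(np.clip(r2, 0.0, 1.0)), n=x.size, wavelength=wavelength,
    )


@dataclass(frozen=True)
class ModelComparison:
    linear: CalibrationModel
    saturating: CalibrationModel
    preferred: Literal["linear", "saturating"]


def compare_models(
    x, y, wavelength: float = DEFAULT_WAVELENGTH, tie_tol: float = 1e-9
) -> ModelComparison:
    """Fit both families and prefer the higher r².

    The saturating family nests the line through the origin, so for truly
    linear data the two r² values coincide to numerical precision; ties
    within ``tie_tol`` resolve to the linear model (parsimony).
    """
    lin = fit_linear(x, y, wavelength=wavelength)
    sat = fit_box_lucas(x, y, wavelength=wavelength)
    if sat.r2 > lin.r2 + tie_tol:
        preferred = "saturating"
    else:
        preferred = "linear"
    return ModelComparison(linear=lin, saturating=sat, preferred=preferred)
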