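"""Per-wavelength correlation scanning.

Algal density proxies (dry biomass, chlorophyll a, Mg, cell counts,
fluorescence) all scale with the dilution series, but the wavelength at
which a spectrophotometer tracks each of them best is not obvious a priori.
The scanner answers that empirically: at every wavelength on a 1 nm grid it
runs a simple linear regression of blank-corrected absorbance against the
chosen laboratory parameter across the dilution series, records slope,
intercept and r² per wavelength, and reports the r²-maximising wavelength.

The regression itself is the closed-form ordinary-least-squares fit with
r² defined as the squared Pearson correlation, so r² is invariant under
swapping predictor and response and under affine rescaling of either axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density import DilutionSeries
from .spectra import SpectraSet, restrict_range

__all__ = ["ScanTable", "simple_linreg", "scan", "best_wavelength"]

logger = logging.getLogger(__name__)

DEFAULT_SCAN_RANGE: tuple[float, float] = (300.0, 1100.0)


class RegressionError(ValueError):
    pass


def simple_linreg(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x.

    Returns ``(slope, intercept, r2)`` with r² the squared Pearson
    correlation.  A constant response is degenerate: the fit is the flat
    line through the mean and r² is defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise RegressionError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise RegressionError(f"need at least 3 points, got {n}")
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    syy = float(ym @ ym)
    sxy = float(xm @ ym)
    if sxx == 0.0:
        raise RegressionError("x is constant; regression undefined")
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy == 0.0:
        return 0.0, float(y.mean()), 0.0
    r2 = sxy * sxy / (sxx * syy)
    return slope, intercept, float(r2)


@dataclass
class ScanTable:
    """Per-wavelength regression results for one laboratory parameter."""

    wavelengths: np.ndarray
    slope: np.ndarray
    intercept: np.ndarray
    r2: np.ndarray
    parameter_name: str
    n_points: np.ndarray

    def __post_init__(self) -> None:
        arrays = (self.slope, self.intercept, self.r2, self.n_points)
        if any(np.asarray(a).shape != np.asarray(self.wavelengths).shape for a in arrays):
            raise ValueError("all ScanTable columns must share one length")
        if np.any((self.r2 < 0) | (self.r2 > 1 + 1e-12)):
            raise ValueError("r2 outside [0, 1]")

    def __len__(self) -> int:
        return int(np.asarray(self.wavelengths).size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "slope": self.slope,
                "intercept": self.intercept,
                "r2": self.r2,
                "n": self.n_points,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def scan(
    spectra: SpectraSet,
    series: DilutionSeries,
    parameter: str,
    wl_range: tuple[float, float] = DEFAULT_SCAN_RANGE,
    step: float | None = None,
) -> ScanTable:
    """Regress absorbance on a density parameter at every wavelength.

    For each dilution retained for ``parameter`` (after its below-LOD
    exclusions) the replicate-averaged, blank-corrected spectrum supplies
    the response; the parameter value is the predictor.  Degenerate columns
    (constant absorbance across dilutions) get r² = 0 with a warning rather
    than aborting the scan, so the output always covers the full grid.
    """
    dilutions, values = series.values(parameter)
    usable = [d for d in dilutions if d in spectra.dilutions]
    vals = [v for d, v in zip(dilutions, values) if d in spectra.dilutions]
    if len(usable) < 3:
        raise RegressionError(
            f"only {len(usable)} usable dilutions for {parameter!r}; need >= 3"
        )
    x = np.asarray(vals, dtype=float)
    if np.ptp(x) == 0:
        raise RegressionError(f"parameter {parameter!r} constant across dilutions")

    corrected = [restrict_range(spectra.corrected(d), *wl_range) for d in usable]
    grid = corrected[0].wavelengths
    if step is not None and step != spectra.step:
        keep = np.isclose((grid - grid[0]) % step, 0) | np.isclose(
            (grid - grid[0]) % step, step
        )
        grid = grid[keep]
        corrected = [restrict_range(s, grid[0], grid[-1]) for s in corrected]
    A = np.vstack([np.interp(grid, s.wavelengths, s.absorbance) for s in corrected])

    n_wl = grid.size
    slopes = np.empty(n_wl)
    intercepts = np.empty(n_wl)
    r2s = np.empty(n_wl)
    n_degenerate = 0
    for j in range(n_wl):
        yj = A[:, j]
        if np.ptp(yj) == 0.0:
            slopes[j], intercepts[j], r2s[j] = 0.0, float(yj.mean()), 0.0
            n_degenerate += 1
            continue
        slopes[j], intercepts[j], r2s[j] = simple_linreg(x, yj)
    if n_degenerate:
        logger.warning(
            "%d/%d wavelengths had constant absorbance; r2 set to 0",
            n_degenerate,
            n_wl,
        )
    return ScanTable(
        wavelengths=grid,
        slope=slopes,
        intercept=intercepts,
        r2=r2s,
        parameter_name=parameter,
        n_points=np.full(n_wl, x.size, dtype=int),
    )


def best_wavelength(
    table: ScanTable, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Wavelength of maximum r², ties broken toward the lowest wavelength."""
    wl = np.asarray(table.wavelengths, dtype=float)
    r2 = np.asarray(table.r2, dtype=float)
    if window is not None:
        lo, hi = window
        mask = (wl >= lo) & (wl <= hi)
        if not mask.any():
            raise RegressionError(f"empty scan window [{lo}, {hi}]")
        wl, r2 = wl[mask], r2[mask]
    i = int(np.argmax(r2))  # first occurrence == lowest wavelength (sorted grid)
    return float(wl[i]), float(r2[i])
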