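"""UV–Vis spectra: containers, file IO, blank correction and querying.

A :class:`Spectrum` is one spectrophotometer scan — an absorbance (optical
density) value per wavelength on a strictly increasing nanometre grid.  A
:class:`SpectraSet` groups the replicate scans of a dilution series together
with the solvent blank, regridded onto a common 1 nm grid so that the
per-wavelength correlation scanner can walk aligned columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Spectrum",
    "SpectraSet",
    "read_spectrum",
    "read_spectra_set",
    "average_replicates",
    "blank_correct",
    "restrict_range",
    "od_at",
    "regrid",
]


class SpectrumError(ValueError):
    """Raised for malformed spectra or invalid spectral operations."""


@dataclass(frozen=True)
class Spectrum:
    """One absorbance scan on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths:
        Wavelength grid in nm, strictly increasing.
    absorbance:
        Dimensionless optical density per wavelength.  Negative values are
        legal (and expected) after blank subtraction.
    replicate_id:
        Free-form label for the scan.
    blank_corrected:
        Whether the solvent blank has already been subtracted.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    replicate_id: str = ""
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1:
            raise SpectrumError("wavelengths and absorbance must be 1-D")
        if wl.size != ab.size:
            raise SpectrumError(
                f"grid length {wl.size} != absorbance length {ab.size}"
            )
        if wl.size == 0:
            raise SpectrumError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ab)):
            raise SpectrumError("non-finite values in spectrum")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def same_grid(self, other: "Spectrum") -> bool:
        return len(self) == len(other) and bool(
            np.array_equal(self.wavelengths, other.wavelengths)
        )


def read_spectrum(
    path: str | Path,
    wavelength_col: str = "wavelength_nm",
    absorbance_col: str = "absorbance",
    replicate_id: str | None = None,
) -> Spectrum:
    """Read a delimited two-column spectrum file (CSV or TSV, header row).

    Rows are sorted by wavelength; duplicate wavelengths are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    for col in (wavelength_col, absorbance_col):
        if col not in df.columns:
            raise SpectrumError(f"{path}: missing column {col!r}")
    wl = pd.to_numeric(df[wavelength_col], errors="coerce")
    ab = pd.to_numeric(df[absorbance_col], errors="coerce")
    if wl.isna().any() or ab.isna().any():
        raise SpectrumError(f"{path}: non-numeric cells in spectrum columns")
    order = np.argsort(wl.to_numpy())
    wl = wl.to_numpy()[order]
    ab = ab.to_numpy()[order]
    if np.any(np.diff(wl) == 0):
        dupes = wl[:-1][np.diff(wl) == 0]
        raise SpectrumError(f"{path}: duplicate wavelengths {np.unique(dupes)}")
    return Spectrum(wl, ab, replicate_id=replicate_id or path.stem)


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of replicate scans on one grid.

    The result is flagged blank-corrected only if every input is.
    """
    if len(spectra) == 0:
        raise SpectrumError("average_replicates requires at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if not s.same_grid(first):
            raise SpectrumError("replicates are on different wavelength grids")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return Spectrum(
        first.wavelengths.copy(),
        mean,
        replicate_id="mean",
        blank_corrected=all(s.blank_corrected for s in spectra),
    )


def blank_correct(sample: Spectrum, blank: Spectrum) -> Spectrum:
    """Subtract the solvent blank from a sample spectrum, pointwise.

    Negative results are kept — clipping would bias low-concentration
    regressions.  Applying the correction twice is an error.
    """
    if sample.blank_corrected:
        raise SpectrumError("spectrum is already blank-corrected")
    if not sample.same_grid(blank):
        raise SpectrumError("sample and blank are on different grids")
    return Spectrum(
        sample.wavelengths.copy(),
        sample.absorbance - blank.absorbance,
        replicate_id=sample.replicate_id,
        blank_corrected=True,
    )


def restrict_range(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep grid points with lo <= wavelength <= hi (inclusive)."""
    if not lo < hi:
        raise SpectrumError(f"invalid range [{lo}, {hi}]")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise SpectrumError(f"no grid points in [{lo}, {hi}] nm")
    return Spectrum(
        s.wavelengths[mask],
        s.absorbance[mask],
        replicate_id=s.replicate_id,
        blank_corrected=s.blank_corrected,
    )


def od_at(s: Spectrum, wavelength: float) -> float:
    """Optical density at a wavelength; linear interpolation off-grid."""
    lo, hi = s.span
    if not lo <= wavelength <= hi:
        raise SpectrumError(
            f"wavelength {wavelength} nm outside spectrum span [{lo}, {hi}]"
        )
    return float(np.interp(wavelength, s.wavelengths, s.absorbance))


def regrid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid inside its span."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.span
    if grid[0] < lo or grid[-1] > hi:
        raise SpectrumError(
            f"target grid [{grid[0]}, {grid[-1]}] exceeds span [{lo}, {hi}]"
        )
    return Spectrum(
        grid,
        np.interp(grid, s.wavelengths, s.absorbance),
        replicate_id=s.replicate_id,
        blank_corrected=s.blank_corrected,
    )


@dataclass
class SpectraSet:
    """Replicate spectra of a dilution series plus the solvent blank.

    Spectra are keyed by ``(dilution_factor, replicate_index)``.  On
    construction every member (and the blank) is regridded by linear
    interpolation onto a common 1 nm grid covering the intersection of all
    spans, so downstream per-wavelength operations see aligned columns.
    """

    spectra: dict[tuple[int, int], Spectrum]
    blank: Spectrum
    step: float = 1.0
    grid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise SpectrumError("SpectraSet requires at least one spectrum")
        members = list(self.spectra.values()) + [self.blank]
        lo = max(s.span[0] for s in members)
        hi = min(s.span[1] for s in members)
        if lo >= hi:
            raise SpectrumError("spectra spans do not overlap")
        start = np.ceil(lo / self.step) * self.step
        self.grid = np.arange(start, hi + 0.5 * self.step, self.step)
        self.spectra = {
            k: regrid(s, self.grid) for k, s in self.spectra.items()
        }
        self.blank = regrid(self.blank, self.grid)

    @property
    def dilutions(self) -> list[int]:
        return sorted({d for d, _ in self.spectra})

    def replicates(self, dilution: int) -> list[Spectrum]:
        reps = [s for (d, _), s in sorted(self.spectra.items()) if d == dilution]
        if not reps:
            raise SpectrumError(f"no spectra for dilution {dilution}")
        return reps

    def corrected(self, dilution: int) -> Spectrum:
        """Replicate-averaged, blank-corrected spectrum for one dilution.

        The blank is subtracted from the replicate average (not per
        replicate); for a pointwise mean the two orders are numerically
        identical, but the averaged-first order is the documented one.
        """
        avg = average_replicates(self.replicates(dilution))
        if avg.blank_corrected:
            return avg
        return blank_correct(avg, self.blank)


def read_spectra_set(manifest_path: str | Path, step: float = 1.0) -> SpectraSet:
    """Load a SpectraSet from a YAML manifest.

    Manifest layout::

        blank: blank.csv
        samples:
          1: [d1_rep1.csv, d1_rep2.csv]
          10: [d10_rep1.csv]

    Relative paths resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, Mapping) or "blank" not in manifest or "samples" not in manifest:
        raise SpectrumError(f"{manifest_path}: manifest needs 'blank' and 'samples' keys")
    root = manifest_path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else root / q

    blank = read_spectrum(_resolve(manifest["blank"]))
    spectra: dict[tuple[int, int], Spectrum] = {}
    for dilution, files in manifest["samples"].items():
        if isinstance(files, str):
            files = [files]
        for i, f in enumerate(files):
            spectra[(int(dilution), i)] = read_spectrum(_resolve(f))
    return SpectraSet(spectra=spectra, blank=blank, step=step)
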