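"""Synthetic spectra, dilution series, and counting-chamber scenes.

Every generator here carries its ground truth, so the scanner, the
calibration fits and the counting pipeline can all be exercised end to end
with known answers.  The spectral forward model is the same saturating law
the calibration module fits, applied independently at each wavelength:

    A(λ, c) = A_max(λ) · (1 − e^(−k(λ)·c)) · (1 + ε),   ε ~ N(0, noise_sd²)

with wavelength profiles shaped by Gaussian pigment peaks.  The default
peaks sit near 440 and 680 nm, imitating the chlorophyll-dominated
landscape of a green-algal suspension qualitatively — they are
illustrative, not measured values.  Noise is multiplicative by default
because residual spread in replicate scans grows with signal; additive
noise is available via ``multiplicative_noise=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .density import DilutionSeries, PARAMETER_COLUMNS
from .spectra import Spectrum, SpectraSet

__all__ = [
    "SpectrumGeneratorConfig",
    "SceneConfig",
    "PAPER_RATIOS",
    "DEFAULT_STOCK",
    "synth_spectrum",
    "synth_dilution_series",
    "synth_scene",
]


class GeneratorError(ValueError):
    pass


#: Dilution ratios of the reference series: stock plus 2x .. 1000x.
PAPER_RATIOS: tuple[float, ...] = (
    1.0, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005, 0.002, 0.001,
)

#: Stock (undiluted) parameter values used as generator defaults, matching
#: the packaged reference series: dry biomass by evaporation/filtration in
#: mg d.m./L, Chl a and Mg in ug/L, cell number in 10^6 cells/L, and RFU.
DEFAULT_STOCK: dict[str, float] = {
    "bme": 960.0,
    "bmf": 770.0,
    "chla": 7515.6,
    "mg": 204.5,
    "cn": 108222.7,
    "rfu": 1689562.0,
}


@dataclass(frozen=True)
class SpectrumGeneratorConfig:
    """Forward model for saturating pigment spectra.

    ``peaks`` are (center nm, width nm, relative strength) Gaussians; the
    shared peak shape (normalised to max 1) modulates both the A_max and k
    profiles above their baselines, so absorbance is most
    concentration-sensitive where pigments absorb most.

    Two noise channels: ``noise_sd`` perturbs each wavelength
    independently (multiplicative by default), while ``scan_offset_sd``
    adds one shared offset per scan, emulating baseline drift between
    cuvette insertions — drift is wavelength-independent, so it degrades
    every wavelength's regression equally.
    """

    peaks: tuple[tuple[float, float, float], ...] = (
        (440.0, 30.0, 1.0),
        (680.0, 25.0, 0.65),
    )
    amax_baseline: float = 0.40
    amax_scale: float = 2.89
    k_baseline: float = 0.00030
    k_scale: float = 0.00190
    grid_lo: float = 300.0
    grid_hi: float = 1100.0
    grid_step: float = 1.0
    noise_sd: float = 0.0
    multiplicative_noise: bool = True
    scan_offset_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for _, _, s in self.peaks):
            raise GeneratorError("peak strengths must be non-negative")
        if self.noise_sd < 0 or self.scan_offset_sd < 0:
            raise GeneratorError("noise sds must be non-negative")
        if self.amax_baseline <= 0 or self.k_baseline <= 0:
            raise GeneratorError("profile baselines must be positive")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_lo, self.grid_hi + 0.5 * self.grid_step,
                         self.grid_step)

    def _shape(self, wl: np.ndarray) -> np.ndarray:
        shape = np.zeros_like(wl, dtype=float)
        for center, width, strength in self.peaks:
            shape += strength * np.exp(-0.5 * ((wl - center) / width) ** 2)
        peak = shape.max()
        return shape / peak if peak > 0 else shape

    def a_max_profile(self, wl: np.ndarray | None = None) -> np.ndarray:
        wl = self.grid if wl is None else np.asarray(wl, dtype=float)
        return self.amax_baseline + self.amax_scale * self._shape(wl)

    def k_profile(self, wl: np.ndarray | None = None) -> np.ndarray:
        wl = self.grid if wl is None else np.asarray(wl, dtype=float)
        return self.k_baseline + self.k_scale * self._shape(wl)

    def sensitivity_argmax(self, concentrations: Sequence[float]) -> float:
        """Wavelength where mean dA/dc over the series is largest.

        dA/dc = A_max(λ)·k(λ)·e^(−k(λ)·c); this is the generator's ground
        truth for where a correlation scan should peak as noise → 0.
        """
        wl = self.grid
        amax = self.a_max_profile(wl)
        k = self.k_profile(wl)
        c = np.asarray(concentrations, dtype=float)[:, None]
        sens = (amax * k * np.exp(-k * c)).mean(axis=0)
        return float(wl[int(np.argmax(sens))])


def synth_spectrum(
    concentration: float,
    cfg: SpectrumGeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    replicate_id: str = "synthetic",
) -> Spectrum:
    """One synthetic blank-corrected spectrum at a given biomass.

    Deterministic for a fixed config seed (a fresh RNG is derived from
    ``cfg.seed`` unless one is passed in).
    """
    cfg = cfg or SpectrumGeneratorConfig()
    if concentration < 0:
        raise GeneratorError("concentration must be non-negative")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    wl = cfg.grid
    clean = cfg.a_max_profile(wl) * (-np.expm1(-cfg.k_profile(wl) * concentration))
    noisy = clean
    if cfg.noise_sd > 0:
        eps = rng.normal(0.0, cfg.noise_sd, size=wl.size)
        noisy = clean * (1.0 + eps) if cfg.multiplicative_noise else clean + eps
    if cfg.scan_offset_sd > 0:
        # per-scan baseline drift: one offset shared by every wavelength
        noisy = noisy + rng.normal(0.0, cfg.scan_offset_sd)
    return Spectrum(wl, noisy, replicate_id=replicate_id, blank_corrected=True)


def synth_dilution_series(
    stock: Mapping[str, float] | None = None,
    ratios: Sequence[float] = PAPER_RATIOS,
    noise_sd: Mapping[str, float] | float = 0.0,
    lod: Mapping[str, float] | None = None,
    n_replicates: int = 2,
    spectrum_cfg: SpectrumGeneratorConfig | None = None,
    seed: int = 0,
) -> tuple[DilutionSeries, SpectraSet]:
    """A dilution series with paired spectra and exact proportional truth.

    Each parameter scales with the dilution ratio from its stock value,
    then optional multiplicative Gaussian noise is applied; values below a
    parameter's LOD are blanked and flagged.  Spectra are generated from
    the implied dry biomass (the ``bme`` track) with ``n_replicates``
    uncorrected replicates per dilution plus a zero blank, so the
    blank-correct-then-average plumbing is exercised.
    """
    import pandas as pd

    stock = dict(DEFAULT_STOCK if stock is None else stock)
    ratios = list(ratios)
    if any(r <= 0 for r in ratios) or len(set(ratios)) != len(ratios):
        raise GeneratorError("ratios must be positive and distinct")
    if "bme" not in stock:
        raise GeneratorError("stock must include 'bme' to drive the spectra")
    rng = np.random.default_rng(seed)
    if not isinstance(noise_sd, Mapping):
        noise_sd = {p: float(noise_sd) for p in stock}
    lod = dict(lod or {})

    dilutions = [int(round(1.0 / r)) for r in ratios]
    rows: dict[str, list] = {"dilution": dilutions, "ratio": ratios}
    lod_flags: dict[str, list] = {}
    for param in PARAMETER_COLUMNS:
        if param not in stock:
            continue
        vals, flags = [], []
        for r in ratios:
            v = stock[param] * r
            sd = noise_sd.get(param, 0.0)
            if sd > 0:
                v *= 1.0 + rng.normal(0.0, sd)
                v = max(v, 0.0)
            below = param in lod and v < lod[param]
            flags.append(below)
            vals.append(np.nan if below else v)
        rows[param] = vals
        lod_flags[param] = flags
    table = pd.DataFrame(rows)
    lod_frame = pd.DataFrame(lod_flags, index=table.index)
    series = DilutionSeries(table=table, lod=lod_frame)

    cfg = spectrum_cfg or SpectrumGeneratorConfig()
    spectra: dict[tuple[int, int], Spectrum] = {}
    for d, r in zip(dilutions, ratios):
        c = stock["bme"] * r
        for rep in range(n_replicates):
            s = synth_spectrum(c, cfg, rng=rng, replicate_id=f"d{d}_r{rep}")
            spectra[(d, rep)] = Spectrum(
                s.wavelengths, s.absorbance,
                replicate_id=s.replicate_id, blank_corrected=False,
            )
    blank = Spectrum(cfg.grid, np.zeros(cfg.grid.size), replicate_id="blank")
    return series, SpectraSet(spectra=spectra, blank=blank, step=cfg.grid_step)


@dataclass(frozen=True)
class SceneConfig:
    """Synthetic counting-chamber field: dark disks on a light ramp.

    Radii are drawn from a clipped normal so true disk areas stay inside
    the default 6–150 px particle-size band; disks are placed by rejection
    sampling with a minimum clearance so they never touch.  Intensities
    are in [0, 1].
    """

    shape: tuple[int, int] = (384, 384)
    n_cells: int = 50
    radius_mean: float = 4.0
    radius_sd: float = 0.8
    radius_bounds: tuple[float, float] = (2.5, 6.0)
    background_level: float = 0.85
    ramp_amplitude: float = 0.12
    cell_contrast: float = 0.45
    noise_sd: float = 5.0 / 255.0
    margin: int = 4
    min_clearance: float = 2.0
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise GeneratorError("n_cells must be non-negative")
        if self.radius_bounds[0] <= 0:
            raise GeneratorError("radii must be positive")
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be non-negative")


def synth_scene(cfg: SceneConfig | None = None) -> tuple[np.ndarray, dict]:
    """Render a scene; returns (image, ground_truth).

    ground_truth holds ``n_cells``, disk ``centroids`` (row, col) and
    ``radii`` in px.  Deterministic under the config seed.  Raises if the
    requested disks cannot be placed without overlap within the attempt
    cap.
    """
    cfg = cfg or SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    nrow, ncol = cfg.shape

    rows, cols = np.mgrid[0:nrow, 0:ncol].astype(float)
    gx, gy = rng.uniform(-1, 1), rng.uniform(-1, 1)
    ramp = cfg.ramp_amplitude * (
        gx * (cols / max(ncol - 1, 1) - 0.5) + gy * (rows / max(nrow - 1, 1) - 0.5)
    )
    image = cfg.background_level + ramp

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    for _ in range(cfg.n_cells):
        placed = False
        for _attempt in range(cfg.max_attempts):
            r = float(np.clip(rng.normal(cfg.radius_mean, cfg.radius_sd),
                              *cfg.radius_bounds))
            pad = r + cfg.margin
            cy = rng.uniform(pad, nrow - 1 - pad)
            cx = rng.uniform(pad, ncol - 1 - pad)
            ok = all(
                np.hypot(cy - py, cx - px) >= r + pr + cfg.min_clearance
                for (py, px), pr in zip(centers, radii)
            )
            if ok:
                centers.append((cy, cx))
                radii.append(r)
                placed = True
                break
        if not placed:
            raise GeneratorError(
                f"could not place disk {len(centers) + 1}/{cfg.n_cells} "
                f"within {cfg.max_attempts} attempts"
            )
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = int(max(cy - r - 1, 0)), int(min(cy + r + 2, nrow))
        x0, x1 = int(max(cx - r - 1, 0)), int(min(cx + r + 2, ncol))
        sub_r = rows[y0:y1, x0:x1]
        sub_c = cols[y0:y1, x0:x1]
        inside = (sub_r - cy) ** 2 + (sub_c - cx) ** 2 <= r * r
        patch = image[y0:y1, x0:x1]
        patch[inside] = patch[inside] - cfg.cell_contrast
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)
    ground_truth = {
        "n_cells": cfg.n_cells,
        "centroids": np.array(centers, dtype=float).reshape(-1, 2),
        "radii": np.array(radii, dtype=float),
    }
    return image, ground_truth
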