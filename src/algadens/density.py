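"""Dilution-series table, pairwise correlations, and derived quantities.

A :class:`DilutionSeries` holds the laboratory density parameters measured
on each member of a dilution series prepared from a dense *Chlorella
vulgaris* stock: dry biomass by evaporation (``bme``) and by filtration
(``bmf``) in mg d.m./L, chlorophyll a (``chla``, µg/L), magnesium (``mg``,
µg/L), cell number (``cn``, 10⁶ cells/L) and relative fluorescence
(``rfu``).  Values reported below the limit of detection are flagged and
excluded from fits parameter by parameter.

From these columns the module derives cellular stoichiometry: since each
chlorophyll-a molecule carries exactly one Mg atom, a measured Mg
concentration converts to a theoretical Chl a concentration through the
molar mass ratio 893.5 / 24.3 ≈ 36.77; biomass over Mg gives the mineral Mg
content of the dry matter, and biomass over cell number the average
single-cell weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DilutionSeries",
    "CorrelationMatrix",
    "FelfoldyCoefficients",
    "load_table3",
    "read_dilution_series",
    "pairwise_correlations",
    "felfoldy_chla",
    "chla_from_mg",
    "mg_per_100g",
    "cell_weight",
    "summarize_derived",
    "CHL_A_MOLAR_MASS",
    "MG_MOLAR_MASS",
    "MG_TO_CHLA_RATIO",
]

#: Molar masses (g/mol) behind the Mg -> Chl a conversion: one Mg atom per
#: chlorophyll-a molecule.
CHL_A_MOLAR_MASS = 893.5
MG_MOLAR_MASS = 24.3
#: Mass of Chl a per mass of Mg, quoted at 2 decimals.
MG_TO_CHLA_RATIO = round(CHL_A_MOLAR_MASS / MG_MOLAR_MASS, 2)  # 36.77

PARAMETER_COLUMNS = ("bme", "bmf", "chla", "mg", "cn", "rfu")
LOD_TOKEN = "<LOD"


class SeriesError(ValueError):
    pass


@dataclass
class DilutionSeries:
    """Per-dilution parameter table with below-LOD censoring flags.

    ``table`` has one row per dilution factor with a ``dilution`` and
    ``ratio`` column (ratio = 1/dilution) plus any of the parameter
    columns; ``lod`` is a same-shaped boolean frame marking values flagged
    below the limit of detection (their numeric cell is NaN).
    """

    table: pd.DataFrame
    lod: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "dilution" not in t.columns or "ratio" not in t.columns:
            raise SeriesError("series table needs 'dilution' and 'ratio' columns")
        if t["dilution"].duplicated().any():
            raise SeriesError("duplicate dilution factors")
        if not np.allclose(t["ratio"], 1.0 / t["dilution"], rtol=1e-6):
            raise SeriesError("ratio column must equal 1/dilution")
        numeric = t.drop(columns=["dilution"]).select_dtypes("number")
        if (numeric < 0).any().any():
            raise SeriesError("parameter values must be non-negative")

    @property
    def parameters(self) -> list[str]:
        return [c for c in self.table.columns if c in PARAMETER_COLUMNS]

    @property
    def dilutions(self) -> list[int]:
        return [int(d) for d in self.table["dilution"]]

    def values(
        self, parameter: str, exclude_lod: bool = True
    ) -> tuple[list[int], np.ndarray]:
        """Usable (dilution, value) pairs for one parameter.

        Below-LOD and missing entries are dropped when ``exclude_lod`` —
        this reproduces the published exclusion policy (evaporation biomass
        loses the 200x–1000x rows, filtration biomass the 1000x row, Mg
        keeps every row).
        """
        if parameter == "ratio":
            return self.dilutions, self.table["ratio"].to_numpy(dtype=float)
        if parameter not in self.table.columns:
            raise SeriesError(f"unknown parameter {parameter!r}")
        vals = self.table[parameter]
        keep = vals.notna()
        if exclude_lod and parameter in self.lod.columns:
            keep &= ~self.lod[parameter].fillna(False)
        dil = [int(d) for d in self.table.loc[keep, "dilution"]]
        return dil, vals[keep].to_numpy(dtype=float)

    def row(self, dilution: int) -> pd.Series:
        match = self.table[self.table["dilution"] == dilution]
        if match.empty:
            raise SeriesError(f"no row for dilution {dilution}")
        return match.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        for col in self.lod.columns:
            out[col] = out[col].astype(object)
            out.loc[self.lod[col].fillna(False), col] = LOD_TOKEN
        out.to_csv(path, index=False)


def read_dilution_series(path: str | Path) -> DilutionSeries:
    """Read a dilution-series CSV; the literal ``<LOD`` token marks censored cells."""
    raw = pd.read_csv(path, dtype=str).apply(lambda s: s.str.strip())
    lod = raw.eq(LOD_TOKEN)
    numeric = raw.mask(lod).apply(pd.to_numeric, errors="raise")
    return DilutionSeries(table=numeric, lod=lod)


def load_table3() -> DilutionSeries:
    """The packaged ten-point *C. vulgaris* dilution-series reference table."""
    with resources.as_file(
        resources.files("algadens.data").joinpath("table3.csv")
    ) as p:
        return read_dilution_series(p)


# ---------------------------------------------------------------------------
# Pairwise correlations (spreadsheet-trendline style family selection)
# ---------------------------------------------------------------------------

_FAMILIES = ("linear", "logarithmic", "exponential")


@dataclass
class PairCorrelation:
    family: str
    r2: float
    r2_by_family: dict[str, float]
    n: int


@dataclass
class CorrelationMatrix:
    """Best-family r² per parameter pair, symmetric, diagonal undefined."""

    pairs: dict[tuple[str, str], PairCorrelation]
    parameters: list[str]

    def get(self, a: str, b: str) -> PairCorrelation:
        key = (a, b) if (a, b) in self.pairs else (b, a)
        return self.pairs[key]

    def to_dataframe(self, decimals: int = 3) -> pd.DataFrame:
        """Presentation table: upper triangle of 'r2 (family-code)' strings."""
        codes = {"linear": "L", "logarithmic": "Lg", "exponential": "Ep"}
        df = pd.DataFrame("-", index=self.parameters, columns=self.parameters)
        for (a, b), pc in self.pairs.items():
            df.loc[a, b] = f"{pc.r2:.{decimals}f} ({codes[pc.family]})"
        return df


def _family_r2(x: np.ndarray, y: np.ndarray, family: str) -> float | None:
    """Trendline r² for one family, in the transformed fitting space.

    Matches spreadsheet trendline behaviour: the logarithmic family is an
    OLS of y on ln x, the exponential family an OLS of ln y on x, with r²
    reported in the space the line was fitted in.
    """
    from .corrscan import simple_linreg  # deferred: corrscan imports this module

    if family == "linear":
        pass
    elif family == "logarithmic":
        if np.any(x <= 0):
            return None
        x = np.log(x)
    elif family == "exponential":
        if np.any(y <= 0):
            return None
        y = np.log(y)
    else:
        raise SeriesError(f"unknown trendline family {family!r}")
    return simple_linreg(x, y)[2]


def pairwise_correlations(
    series: DilutionSeries,
    parameters: Iterable[str] | None = None,
    families: Iterable[str] = _FAMILIES,
) -> CorrelationMatrix:
    """Best-fitting trendline family and its r² for every parameter pair.

    Uses complete cases after below-LOD exclusion; each pair needs at least
    3 shared dilutions.
    """
    params = list(parameters) if parameters is not None else (
        ["ratio"] + series.parameters
    )
    families = list(families)
    pairs: dict[tuple[str, str], PairCorrelation] = {}
    for i, a in enumerate(params):
        for b in params[i + 1:]:
            da, va = series.values(a)
            db, vb = series.values(b)
            shared = [d for d in da if d in db]
            if len(shared) < 3:
                raise SeriesError(
                    f"only {len(shared)} complete pairs for ({a}, {b})"
                )
            xa = np.array([va[da.index(d)] for d in shared])
            xb = np.array([vb[db.index(d)] for d in shared])
            by_family = {}
            for fam in families:
                r2 = _family_r2(xa, xb, fam)
                if r2 is not None:
                    by_family[fam] = r2
            best = max(by_family, key=by_family.get)
            pairs[(a, b)] = PairCorrelation(
                family=best,
                r2=by_family[best],
                r2_by_family=by_family,
                n=len(shared),
            )
    return CorrelationMatrix(pairs=pairs, parameters=params)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FelfoldyCoefficients:
    """Coefficients of the trichromatic methanol-extract Chl a formula.

    The formula is a turbidity-corrected linear combination of extract
    absorbances:  chla = (c1·(A666 − A750) − c2·(A653 − A750))·factor.
    No default constants ship — supply the values for your extraction
    protocol and pathlength.
    """

    c1: float
    c2: float
    factor: float = 1.0


def felfoldy_chla(
    a750: float, a666: float, a653: float, coeffs: FelfoldyCoefficients
) -> float:
    """Chlorophyll a (µg/L) from methanol-extract absorbances.

    A750 carries no pigment signal and is subtracted from both pigment
    wavelengths as a turbidity correction, so the result is homogeneous of
    degree 1 in the corrected absorbances.
    """
    if coeffs is None:
        raise SeriesError("Felfoldy coefficients are required (no defaults ship)")
    return (coeffs.c1 * (a666 - a750) - coeffs.c2 * (a653 - a750)) * coeffs.factor


def chla_from_mg(mg_conc: float, ratio: float = MG_TO_CHLA_RATIO) -> float:
    """Theoretical Chl a (µg/L) from Mg concentration (µg/L).

    One Mg atom per Chl a molecule: multiply by the molar mass ratio
    893.5/24.3 (36.77 at 2 decimals).  Upper bound in practice — it assumes
    every Mg atom in the biomass sits in a chlorophyll ring.
    """
    mg_conc = np.asarray(mg_conc, dtype=float)
    if np.any(mg_conc < 0):
        raise SeriesError("Mg concentration must be non-negative")
    out = mg_conc * ratio
    return float(out) if out.ndim == 0 else out


def mg_per_100g(mg_conc: float, biomass: float) -> float:
    """Mineral Mg content of the dry matter, mg per 100 g d.m.

    mg_conc in µg/L over biomass in mg d.m./L; the µg/mg and /100 g factors
    cancel to a plain ratio times 100.
    """
    if np.any(np.asarray(biomass) <= 0):
        raise SeriesError("biomass must be positive")
    out = np.asarray(mg_conc, dtype=float) / np.asarray(biomass, dtype=float) * 100.0
    return float(out) if out.ndim == 0 else out


def cell_weight(biomass: float, cells: float) -> float:
    """Average single-cell weight, µg per 10⁶ cells.

    biomass in mg d.m./L (×1000 → µg/L) over cell number in 10⁶ cells/L.
    """
    if np.any(np.asarray(cells) <= 0):
        raise SeriesError("cell number must be positive")
    out = np.asarray(biomass, dtype=float) * 1000.0 / np.asarray(cells, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class DerivedSummary:
    """Per-row derived quantities and their mean ± sample sd."""

    per_row: pd.DataFrame
    mg_per_100g_mean: float
    mg_per_100g_sd: float
    cell_weight_mean: float
    cell_weight_sd: float


def summarize_derived(
    series: DilutionSeries, max_dilution: int = 10
) -> DerivedSummary:
    """Derived Mg content, Chl a-from-Mg and cell weight over the dense rows.

    Only dilutions up to ``max_dilution`` enter: at high dilution the
    evaporation residue and ashed Mg are too close to instrument noise for
    a stoichiometric summary.  Mean and sample standard deviation (ddof=1)
    are taken over the included rows; a single row yields sd = 0 with a
    warning.
    """
    t = series.table
    rows = t[t["dilution"] <= max_dilution].copy()
    required = {"bme", "mg", "cn"}
    missing = required - set(rows.columns)
    if missing:
        raise SeriesError(f"missing columns for derived summary: {sorted(missing)}")
    if rows.empty:
        raise SeriesError(f"no rows at dilution <= {max_dilution}")
    rows["mg_per_100g"] = mg_per_100g(
        rows["mg"].to_numpy(), rows["bme"].to_numpy()
    )
    rows["chla_from_mg"] = chla_from_mg(rows["mg"].to_numpy())
    rows["cell_weight"] = cell_weight(
        rows["bme"].to_numpy(), rows["cn"].to_numpy()
    )
    def _sd(v: pd.Series) -> float:
        if len(v) < 2:
            warnings.warn("single included row: sd reported as 0", stacklevel=2)
            return 0.0
        return float(v.std(ddof=1))

    keep = ["dilution", "ratio", "bme", "mg", "cn",
            "mg_per_100g", "chla_from_mg", "cell_weight"]
    if "chla" in rows.columns:
        keep.insert(5, "chla")
    return DerivedSummary(
        per_row=rows[keep].reset_index(drop=True),
        mg_per_100g_mean=float(rows["mg_per_100g"].mean()),
        mg_per_100g_sd=_sd(rows["mg_per_100g"]),
        cell_weight_mean=float(rows["cell_weight"].mean()),
        cell_weight_sd=_sd(rows["cell_weight"]),
    )
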