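"""Microarray screen ingestion, intensity ranking and K_D fitting.

A screen is a table of spots (peptide sequence, incubation window, grid
position, fluorescence intensity); each window was incubated at one analyte
concentration.  Replicate spots of a peptide are aggregated by median
(robust to scanner speckle; mean available).  Titrations assembled across
a dilution series are fitted to the one-site Langmuir binding isotherm

    I_obs = I_sat * n / (K_D + n)

where ``n`` is the molar analyte concentration, ``I_sat`` the saturation
intensity and ``K_D`` the equilibrium dissociation constant — the
concentration at which half the sites are occupied, so I(n = K_D) is
exactly I_sat / 2.  Fits whose K_D lies far beyond the highest tested
concentration are extrapolations and are flagged unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

#: Molar mass of an IgG1 antibody (rituximab), Da; used to convert dosing
#: in ug/mL into molar units.  Configurable everywhere it is used.
DEFAULT_ANTIBODY_MASS_DA = 145_000.0

#: Two-fold dilution series used for titration experiments, ug/mL.
DILUTION_SERIES_UG_ML = (200.0, 100.0, 50.0, 25.0, 12.5, 6.25, 3.125, 1.5625)

REQUIRED_COLUMNS = ("sequence", "window", "x", "y", "intensity")


class FitError(RuntimeError):
    """Non-convergent binding fit; carries the last iterate."""

    def __init__(self, message: str, last_iterate: tuple[float, float]):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class ArrayScreen:
    """Validated spot-intensity table with free-text scan metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"screen table missing required columns: {missing}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("negative intensities in screen table")
        if "concentration_ug_ml" in self.data.columns:
            if (self.data["concentration_ug_ml"] <= 0).any():
                raise ValueError("non-positive analyte concentration")

    def __len__(self) -> int:
        return len(self.data)

    def aggregated(self, agg: str = "median") -> pd.Series:
        """Per-peptide intensity with replicate spots collapsed."""
        return self.data.groupby("sequence")["intensity"].agg(agg)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class TitrationSeries:
    """(concentration, intensity) pairs for one peptide, molar units (nM)."""

    peptide: str
    concentrations_nM: np.ndarray
    intensities: np.ndarray
    missing_windows: tuple = ()

    def __post_init__(self) -> None:
        if np.any(self.concentrations_nM <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(self.concentrations_nM) != len(self.intensities):
            raise ValueError("concentration/intensity length mismatch")


@dataclass(frozen=True)
class BindingFit:
    """Langmuir fit result for one peptide."""

    peptide: str
    kd_nM: float
    i_sat: float
    rss: float
    reliable: bool
    flag: str = ""


def langmuir(n, kd: float, i_sat: float):
    """One-site binding isotherm I(n) = I_sat * n / (K_D + n)."""
    n = np.asarray(n, dtype=float)
    return i_sat * n / (kd + n)


def read_screen_table(path, column_map: Mapping[str, str] | None = None) -> ArrayScreen:
    """Read a spot table from TSV.

    ``column_map`` renames source columns (e.g. a scanner-export layout)
    onto the required ``sequence/window/x/y/intensity`` names.  Rows whose
    intensity does not parse as a number are rejected with their line
    numbers; a negative intensity is an error.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    intens = pd.to_numeric(df["intensity"], errors="coerce")
    bad = intens.isna()
    if bad.any():
        lines = [i + 2 for i in df.index[bad]]  # +2: header + 1-based
        warnings.warn(f"{path}: rejected {bad.sum()} malformed rows at lines {lines}")
        df = df[~bad].copy()
        intens = intens[~bad]
    df["intensity"] = intens.astype(float)
    for col in ("x", "y"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "concentration_ug_ml" in df.columns:
        df["concentration_ug_ml"] = pd.to_numeric(df["concentration_ug_ml"])
    return ArrayScreen(df.reset_index(drop=True))


def rank_by_intensity(screen: ArrayScreen, agg: str = "median") -> pd.DataFrame:
    """Descending-intensity peptide ranking with ratio to the maximum.

    Replicate spots are aggregated first; ties share neighbouring ranks in
    lexicographic peptide order.  Ranking and ratios are invariant under
    rescaling all intensities by a positive constant.
    """
    agg_int = screen.aggregated(agg)
    if agg_int.empty:
        raise ValueError("empty screen")
    df = agg_int.reset_index().sort_values(
        ["intensity", "sequence"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    max_int = df["intensity"].iloc[0]
    if max_int == 0:
        warnings.warn("all-zero screen: ratios undefined, reported as 0")
        df["ratio"] = 0.0
    else:
        df["ratio"] = df["intensity"] / max_int
    return df.reset_index(drop=True)


def intensity_property_trace(
    screen: ArrayScreen,
    property_values: Mapping[str, float] | pd.Series,
    smooth_window: int = 101,
    agg: str = "median",
) -> pd.DataFrame:
    """Property values of peptides ordered by ascending signal intensity.

    The rolling-median smoothed column is the "line through neighbouring
    peptides of growing intensity" used to visualise composition trends;
    it is descriptive output, not an inference.
    """
    agg_int = screen.aggregated(agg).sort_values(kind="mergesort")
    props = pd.Series(property_values)
    out = pd.DataFrame(
        {
            "sequence": agg_int.index,
            "intensity": agg_int.values,
            "property": props.reindex(agg_int.index).values,
        }
    )
    out["smoothed"] = (
        out["property"].rolling(smooth_window, center=True, min_periods=1).median()
    )
    return out


def mass_to_molar(c_ug_ml: float, antibody_mass_da: float = DEFAULT_ANTIBODY_MASS_DA) -> float:
    """Convert an analyte dose in ug/mL into nM given its molar mass in Da."""
    if c_ug_ml <= 0 or antibody_mass_da <= 0:
        raise ValueError("concentration and molar mass must be positive")
    return c_ug_ml / antibody_mass_da * 1e6


def assemble_titrations(
    screens: Mapping[object, ArrayScreen],
    window_concentrations_ug_ml: Mapping[object, float],
    antibody_mass_da: float = DEFAULT_ANTIBODY_MASS_DA,
    agg: str = "median",
) -> dict[str, TitrationSeries]:
    """One titration series per peptide across the incubation windows.

    Windows hold identical sublibraries incubated at different analyte
    concentrations.  A peptide absent from some window keeps its series
    with that window flagged as missing.  The result is invariant to the
    order in which windows are supplied.
    """
    per_window: dict[object, pd.Series] = {
        w: s.aggregated(agg) for w, s in screens.items()
    }
    all_peptides = sorted(set().union(*(s.index for s in per_window.values())))
    ordered = sorted(window_concentrations_ug_ml, key=lambda w: window_concentrations_ug_ml[w])
    out: dict[str, TitrationSeries] = {}
    for pep in all_peptides:
        ns, ints, missing = [], [], []
        for w in ordered:
            if w not in per_window or pep not in per_window[w].index:
                missing.append(w)
                continue
            ns.append(mass_to_molar(window_concentrations_ug_ml[w], antibody_mass_da))
            ints.append(float(per_window[w].loc[pep]))
        out[pep] = TitrationSeries(
            pep, np.asarray(ns), np.asarray(ints), tuple(missing)
        )
    return out


def fit_kd(
    series: TitrationSeries,
    reliability_factor: float = 3.0,
    weighting: str | None = None,
    tol: float = 1e-8,
) -> BindingFit:
    """Least-squares Langmuir fit of a titration series.

    Minimises ``sum((I_obs - I_sat*n/(K_D+n))**2)`` (optionally with 1/I
    weights) with positivity enforced through bounds.  Initialisation:
    I_sat at the maximum observed intensity, K_D at the median tested
    concentration.  The fit is flagged unreliable when the series is flat
    or when K_D exceeds ``reliability_factor`` times the highest tested
    concentration (an extrapolation beyond the data).
    """
    n = series.concentrations_nM
    I = series.intensities
    if len(n) < 3:
        raise ValueError("need at least 3 titration points")
    if len(np.unique(n)) < 2:
        raise ValueError("need at least 2 distinct concentrations")
    flat = np.ptp(I) == 0
    i_sat0 = float(I.max()) if I.max() > 0 else 1.0
    kd0 = float(np.median(n))

    if weighting == "inverse_intensity":
        w = 1.0 / np.maximum(I, np.max(I) * 1e-6)
    elif weighting is None:
        w = np.ones_like(I)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    def resid(params):
        kd, i_sat = params
        return (langmuir(n, kd, i_sat) - I) * np.sqrt(w)

    res = least_squares(
        resid,
        x0=[kd0, i_sat0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=10_000,
    )
    if not res.success:
        raise FitError(f"binding fit did not converge for {series.peptide!r}", tuple(res.x))
    kd, i_sat = map(float, res.x)
    rss = float(np.sum((langmuir(n, kd, i_sat) - I) ** 2))
    flag = ""
    if flat:
        flag = "flat series"
    elif kd > reliability_factor * n.max():
        flag = f"K_D beyond {reliability_factor:g}x max tested concentration"
    return BindingFit(series.peptide, kd, i_sat, rss, reliable=not flag, flag=flag)


def classify_binders(
    fits: Sequence[BindingFit], threshold_nM: float = 1000.0
) -> list[BindingFit]:
    """Reliable fits with K_D at or below the threshold, ascending by K_D."""
    hits = [f for f in fits if f.reliable and f.kd_nM <= threshold_nM]
    return sorted(hits, key=lambda f: (f.kd_nM, f.peptide))


def fits_to_frame(fits: Sequence[BindingFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [f.peptide for f in fits],
            "KD_nM": [f.kd_nM for f in fits],
            "Isat": [f.i_sat for f in fits],
            "rss": [f.rss for f in fits],
            "reliable": [f.reliable for f in fits],
        }
    )
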