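"""Synthetic proteomes and screens with known ground truth.

Two features of real data drive the design here.  First, proteomes are not
uniform: short motifs repeated in large protein families (zinc-finger
linkers, poly-acidic and poly-proline runs) dominate fragment occurrence
counts and therefore dominate coverage-weighted library selection — the
generator plants configurable motif spikes on top of a uniform residue
background to emulate that.  Second, screen intensities follow a one-site
Langmuir isotherm with multiplicative (lognormal) noise, and affinity in
the simulated screen is driven by hydrophobic content: the latent K_D of a
peptide falls by a constant fold per Trp/Phe residue.  Ground truth is
emitted alongside every simulated screen so parameter recovery can be
measured exactly.

Every generator is a pure function of its config: a fixed seed yields
byte-identical output; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptidome import CANONICAL_AA, ProteinRecord
from .properties import count_residues
from .screen import (
    DEFAULT_ANTIBODY_MASS_DA,
    DILUTION_SERIES_UG_ML,
    ArrayScreen,
    langmuir,
    mass_to_molar,
)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic proteome / screen generators.

    ``motif_spikes`` is a tuple of (motif, copies): each copy overwrites a
    random non-overlapping stretch of a random protein, so the motif's
    occurrence count is at least ``copies``.  The binding model: latent
    K_D = ``baseline_kd_nM`` / ``wf_fold`` ** (number of W and F residues);
    spot intensity = Langmuir value at the window concentration times a
    unit-mean lognormal factor with coefficient of variation ``noise_cv``.
    """

    seed: int
    n_proteins: int = 30
    length_min: int = 30
    length_max: int = 120
    motif_spikes: tuple[tuple[str, int], ...] = ()
    baseline_kd_nM: float = 2000.0
    wf_fold: float = 2.0
    i_sat: float = 50_000.0
    noise_cv: float = 0.05
    concentrations_ug_ml: tuple[float, ...] = DILUTION_SERIES_UG_ML
    antibody_mass_da: float = DEFAULT_ANTIBODY_MASS_DA

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_proteins < 1 or self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("invalid protein count / length bounds")
        for val in (self.baseline_kd_nM, self.wf_fold, self.i_sat, self.antibody_mass_da):
            if val <= 0:
                raise ValueError("binding-model parameters must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def synth_proteome(config: FixtureConfig) -> list[ProteinRecord]:
    """Uniform-residue proteome with planted motif repeats.

    Spike placements never overlap one another, so each motif occurs at
    least its configured number of times (chance background occurrences
    can only add).
    """
    rng = np.random.default_rng(config.seed)
    lengths = rng.integers(config.length_min, config.length_max + 1, config.n_proteins)
    aa = np.array(list(CANONICAL_AA))
    seqs = [list(rng.choice(aa, size=L)) for L in lengths]
    reserved: list[list[tuple[int, int]]] = [[] for _ in seqs]
    for motif, copies in config.motif_spikes:
        m = len(motif)
        for _ in range(copies):
            placed = False
            for _attempt in range(200):
                p = int(rng.integers(0, config.n_proteins))
                if len(seqs[p]) < m:
                    continue
                start = int(rng.integers(0, len(seqs[p]) - m + 1))
                if all(start + m <= a or start >= b for a, b in reserved[p]):
                    seqs[p][start : start + m] = list(motif)
                    reserved[p].append((start, start + m))
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"could not place motif {motif!r}: proteome too small for spikes"
                )
    return [
        ProteinRecord(f"SYN{idx:05d}", "".join(s)) for idx, s in enumerate(seqs, 1)
    ]


def latent_kd(peptide: str, config: FixtureConfig) -> float:
    """Ground-truth dissociation constant of the hydrophobicity-driven model."""
    return config.baseline_kd_nM / config.wf_fold ** count_residues(peptide, "WF")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    # mean of the factor is exactly 1
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def synth_screen(
    peptides: list[str], config: FixtureConfig
) -> tuple[dict[int, ArrayScreen], pd.DataFrame]:
    """Simulated multi-window dilution-series screen plus ground truth.

    Returns one :class:`ArrayScreen` per window (windows numbered from 1,
    highest concentration first, matching the dilution series order) and a
    table of the latent per-peptide K_D and I_sat values.
    """
    rng = np.random.default_rng(config.seed)
    kds = np.array([latent_kd(p, config) for p in peptides])
    ncols = max(int(np.ceil(np.sqrt(len(peptides)))), 1)
    screens: dict[int, ArrayScreen] = {}
    for w, c_ug in enumerate(config.concentrations_ug_ml, start=1):
        n_nM = mass_to_molar(c_ug, config.antibody_mass_da)
        ideal = langmuir(n_nM, kds, config.i_sat)
        noisy = ideal * _lognormal_factors(rng, config.noise_cv, len(peptides))
        df = pd.DataFrame(
            {
                "sequence": peptides,
                "window": w,
                "x": np.arange(len(peptides)) % ncols,
                "y": np.arange(len(peptides)) // ncols,
                "intensity": noisy,
                "concentration_ug_ml": c_ug,
            }
        )
        screens[w] = ArrayScreen(df, {"simulated": True, "seed": config.seed})
    truth = pd.DataFrame(
        {"peptide": peptides, "kd_nM": kds, "i_sat": config.i_sat}
    )
    return screens, truth


def synth_titrations(
    n_series: int,
    seed: int,
    kd_range_nM: tuple[float, float] = (50.0, 5000.0),
    i_sat: float = 50_000.0,
    noise_cv: float = 0.05,
    concentrations_ug_ml: tuple[float, ...] = DILUTION_SERIES_UG_ML,
    antibody_mass_da: float = DEFAULT_ANTIBODY_MASS_DA,
) -> list[tuple["TitrationSeries", float]]:
    """Seeded titration curves with log-uniform ground-truth K_D.

    Each series evaluates the Langmuir isotherm at the dilution-series
    concentrations (converted to nM at the configured antibody mass) and
    applies unit-mean lognormal noise with the given CV.  Returns
    ``(series, true_kd_nM)`` pairs for parameter-recovery studies.
    """
    from .screen import TitrationSeries

    rng = np.random.default_rng(seed)
    lo, hi = kd_range_nM
    kds = np.exp(rng.uniform(np.log(lo), np.log(hi), n_series))
    ns = np.array([mass_to_molar(c, antibody_mass_da) for c in concentrations_ug_ml])
    out = []
    for i, kd in enumerate(kds):
        ideal = langmuir(ns, kd, i_sat)
        noisy = ideal * _lognormal_factors(rng, noise_cv, len(ns))
        out.append((TitrationSeries(f"sim{i:04d}", ns, noisy), float(kd)))
    return out


def window_concentration_map(config: FixtureConfig) -> dict[int, float]:
    """Window id -> incubation concentration (ug/mL) for a simulated screen."""
    return {w: c for w, c in enumerate(config.concentrations_ug_ml, start=1)}


def synth_substitution_screen(
    origin: str,
    invariant_positions: dict[int, tuple[str, ...]],
    seed: int,
    high: float = 10_000.0,
    low: float = 100.0,
    noise_cv: float = 0.05,
) -> ArrayScreen:
    """Substitution-array screen simulated from a ground-truth motif.

    Cells whose residue is allowed at an invariant position, and every cell
    of a free position, emit ``high`` intensity; disallowed cells at
    invariant positions emit ``low``.  Multiplicative lognormal noise is
    applied; the high/low gap should stay well above the noise for exact
    motif recovery.
    """
    from .substitution import SubstitutionSpec, generate_substitution_library

    rng = np.random.default_rng(seed)
    spec = SubstitutionSpec(origin)
    variants = generate_substitution_library(spec)
    rows = []
    for i, var in enumerate(variants):
        allowed = invariant_positions.get(var.position)
        retains = allowed is None or var.aa in allowed or var.is_original
        base = high if retains else low
        rows.append(
            {
                "sequence": var.sequence,
                "window": 1,
                "x": i % 20,
                "y": i // 20,
                "intensity": base * _lognormal_factors(rng, noise_cv, 1)[0],
                "position": var.position,
            }
        )
    return ArrayScreen(pd.DataFrame(rows), {"simulated": True, "seed": seed})
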