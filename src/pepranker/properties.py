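"""Per-peptide physicochemical descriptors.

Summed charge (SQ), summed average molecular mass, summed Wimley-White
whole-residue hydrophobicity (SH), summed helix propensity (HP) and residue
counts — the additive annotations used to relate array signal intensity to
peptide composition.  All descriptors are sums of per-residue constants, so
they are additive under concatenation and invariant under residue
permutation; none makes a conformational claim.

Scale provenance
----------------
* ``mass``: standard average residue masses (Da); a free peptide adds one
  water (18.02 Da).
* ``wimley_white_interface`` / ``wimley_white_octanol``: whole-residue
  transfer free-energy scales of Wimley & White (POPC bilayer interface,
  resp. n-octanol), stored with the sign flipped so that larger values mean
  more hydrophobic (Trp and Phe largest).  Units kcal/mol.
* ``helix_propensity``: Pace & Scholtz helix propensities in kcal/mol
  relative to alanine (0.0); larger values disfavour the helix.

The tables are frozen: a SHA-256 checksum of each is recorded and verified
by the test suite so annotation output is reproducible across releases.
"""

from __future__ import annotations

import hashlib
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .peptidome import CANONICAL_AA, CANONICAL_SET

#: Charge convention: Arg, Lys and His count +1; Asp and Glu count -1;
#: termini are ignored (array peptides are surface-coupled).
POSITIVE_AA = frozenset("RKH")
NEGATIVE_AA = frozenset("DE")

#: Average residue (amino acid minus water) masses, Da.
RESIDUE_MASS_DA = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}

WATER_MASS_DA = 18.02

#: Wimley-White whole-residue scales, kcal/mol, sign-flipped transfer free
#: energies (water -> POPC interface; water -> n-octanol) so that larger =
#: more hydrophobic.  Asp/Glu charged, His neutral.
WIMLEY_WHITE_INTERFACE = {
    "A": -0.17, "C": 0.24, "D": -1.23, "E": -2.02, "F": 1.13,
    "G": -0.01, "H": -0.17, "I": 0.31, "K": -0.99, "L": 0.56,
    "M": 0.23, "N": -0.42, "P": -0.45, "Q": -0.58, "R": -0.81,
    "S": -0.13, "T": -0.14, "V": -0.07, "W": 1.85, "Y": 0.94,
}

WIMLEY_WHITE_OCTANOL = {
    "A": -0.50, "C": 0.02, "D": -3.64, "E": -3.63, "F": 1.71,
    "G": -1.15, "H": -0.11, "I": 1.12, "K": -2.80, "L": 1.25,
    "M": 0.67, "N": -0.85, "P": -0.14, "Q": -0.77, "R": -1.81,
    "S": -0.46, "T": -0.25, "V": 0.46, "W": 2.09, "Y": 0.71,
}

#: Helix propensity, kcal/mol relative to Ala = 0 (Pace & Scholtz).
HELIX_PROPENSITY = {
    "A": 0.00, "C": 0.68, "D": 0.69, "E": 0.40, "F": 0.54,
    "G": 1.00, "H": 0.61, "I": 0.41, "K": 0.26, "L": 0.21,
    "M": 0.24, "N": 0.65, "P": 3.16, "Q": 0.39, "R": 0.21,
    "S": 0.50, "T": 0.66, "V": 0.61, "W": 0.49, "Y": 0.53,
}

HYDROPHOBICITY_SCALES = {
    "interface": WIMLEY_WHITE_INTERFACE,
    "octanol": WIMLEY_WHITE_OCTANOL,
}


def scale_checksum(scale: dict[str, float]) -> str:
    """SHA-256 over the canonical (sorted, 2-decimal) rendering of a scale."""
    text = ";".join(f"{aa}:{scale[aa]:.2f}" for aa in sorted(scale))
    return hashlib.sha256(text.encode()).hexdigest()


#: Frozen checksums of the embedded tables (verified by the test suite).
FROZEN_CHECKSUMS = {
    "mass": "c53a73ba1178de560225b234268ccdb0bb45cc569a90f81cd121312b12140d7a",
    "interface": "d0b57104446b9b4c25aa919b82ee352dddf7c9543742a1d4b6dcf3fd9e108a83",
    "octanol": "01930fb6ecf8545bf2ade2b736123ad8ab0e7df24759669f891d64f7d7ff972f",
    "helix": "277a9b8de3d009994f9128fe3bd6a69df89cc1ba77700fe5b890050f61a98293",
}


def _check_canonical(peptide: str) -> None:
    bad = set(peptide) - CANONICAL_SET
    if bad:
        raise ValueError(f"non-canonical residues {sorted(bad)} in {peptide!r}")


def sum_charge(peptide: str) -> int:
    """Net charge in elementary charges: (#R + #K + #H) - (#D + #E)."""
    _check_canonical(peptide)
    return sum(1 for c in peptide if c in POSITIVE_AA) - sum(
        1 for c in peptide if c in NEGATIVE_AA
    )


def sum_mass(peptide: str, include_water: bool = True) -> float:
    """Average molecular mass in Da (one water for the free peptide)."""
    _check_canonical(peptide)
    m = sum(RESIDUE_MASS_DA[c] for c in peptide)
    return m + WATER_MASS_DA if include_water else m


def sum_hydrophobicity(peptide: str, scale: str = "interface") -> float:
    """Summed Wimley-White whole-residue hydrophobicity, kcal/mol."""
    _check_canonical(peptide)
    table = HYDROPHOBICITY_SCALES[scale]
    return sum(table[c] for c in peptide)


def sum_helix_propensity(peptide: str) -> float:
    """Summed helix propensity, kcal/mol (relative to poly-Ala = 0)."""
    _check_canonical(peptide)
    return sum(HELIX_PROPENSITY[c] for c in peptide)


def count_residues(peptide: str, subset: Iterable[str]) -> int:
    """Number of residues of ``peptide`` belonging to ``subset``."""
    subset = frozenset(subset)
    return sum(1 for c in peptide if c in subset)


def annotate(peptides: Sequence[str], hydrophobicity_scale: str = "interface") -> pd.DataFrame:
    """Full property table: peptide, SQ, mass, SH, HP and per-residue counts."""
    rows = []
    for p in peptides:
        row = {
            "peptide": p,
            "SQ": sum_charge(p),
            "mass": round(sum_mass(p), 2),
            "SH": round(sum_hydrophobicity(p, hydrophobicity_scale), 2),
            "HP": round(sum_helix_propensity(p), 2),
        }
        for aa in CANONICAL_AA:
            row[f"n_{aa}"] = p.count(aa)
        rows.append(row)
    return pd.DataFrame(rows)


def integral_charge_curve(peptides: Sequence[str] | "pd.Series") -> np.ndarray:
    """Running sum of SQ over peptides in library (rank) order.

    A change in slope along the curve marks a change in the mean charge
    regime of the ranked library.
    """
    charges = np.array([sum_charge(p) for p in peptides], dtype=np.int64)
    return np.cumsum(charges)
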