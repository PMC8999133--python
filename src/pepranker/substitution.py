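"""Positional substitution libraries, matrices and epitope-motif calls.

A substitutional analysis measures binding for every single-position
replacement of an origin peptide: one array spot per (position, residue)
cell, twenty residues by L positions — the original residue included at
each position, so the origin sequence is spotted L times.  The resulting
20 x L intensity grid locates the residues that carry binding: a position
where (almost) no foreign residue retains the original signal is invariant,
and the invariant positions with their allowed residue sets compose the
epitope motif (freely substitutable positions render as ``x``).

Cyclic peptides (e.g. head-to-tail thioether macrocycles mimicking a
disulfide-constrained loop) are handled purely at the sequence level via a
cyclization descriptor carried on every variant; enumeration and motif
calling are identical to the linear case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .peptidome import CANONICAL_AA
from .screen import ArrayScreen

#: Fixed amino-acid row order (alphabetical one-letter codes) so matrix
#: outputs are bit-exact across runs.
AA_ROW_ORDER = tuple(CANONICAL_AA)


@dataclass(frozen=True)
class SubstitutionSpec:
    """What to substitute: origin peptide, positions, alphabet, cyclization."""

    origin: str
    positions: tuple[int, ...] | None = None  # 1-based; None = all
    alphabet: tuple[str, ...] = AA_ROW_ORDER
    cyclization: str | None = None  # e.g. "head-to-tail thioether"

    def __post_init__(self) -> None:
        if not self.origin:
            raise ValueError("empty origin peptide")
        if not self.alphabet:
            raise ValueError("empty substitution alphabet")
        if self.positions is not None:
            bad = [p for p in self.positions if not 1 <= p <= len(self.origin)]
            if bad:
                raise ValueError(f"positions out of range: {bad}")

    @property
    def resolved_positions(self) -> tuple[int, ...]:
        return self.positions or tuple(range(1, len(self.origin) + 1))


@dataclass(frozen=True)
class Variant:
    """One substitution spot: the sequence with ``aa`` at ``position``."""

    sequence: str
    position: int  # 1-based
    aa: str
    is_original: bool
    cyclization: str | None = None


def generate_substitution_library(spec: SubstitutionSpec) -> list[Variant]:
    """All (position, residue) variants of the origin peptide.

    A full spec over a length-L peptide and the 20 canonical residues
    yields L*20 variants; the originals coincide in sequence, so only
    L*19 + 1 sequences are distinct.
    """
    out = []
    for pos in spec.resolved_positions:
        for aa in spec.alphabet:
            seq = spec.origin[: pos - 1] + aa + spec.origin[pos:]
            out.append(
                Variant(seq, pos, aa, aa == spec.origin[pos - 1], spec.cyclization)
            )
    return out


@dataclass(frozen=True)
class SubstitutionMatrix:
    """20 x L intensity grid for the substitution library of one peptide.

    ``grid`` rows are amino acids in fixed alphabetical order, columns are
    1-based positions; NaN marks a gapped (unmeasured) cell.
    """

    origin: str
    grid: pd.DataFrame
    n_gaps: int = 0

    @property
    def original_cells(self) -> list[tuple[str, int]]:
        """(amino acid, position) cells spelling the origin sequence."""
        return [(aa, i + 1) for i, aa in enumerate(self.origin)]

    def origin_intensities(self) -> np.ndarray:
        return np.array([self.grid.at[aa, pos] for aa, pos in self.original_cells])

    def write_tsv(self, path) -> None:
        out = self.grid.copy()
        out.index.name = "aa"
        out.to_csv(path, sep="\t")


def build_substitution_matrix(
    screen: ArrayScreen,
    spec: SubstitutionSpec,
    agg: str = "median",
    max_gap_fraction: float = 0.2,
) -> SubstitutionMatrix:
    """Populate the grid from variant spots matched by sequence + position.

    The screen table must carry a ``position`` column (1-based substituted
    position) alongside the usual spot columns, because the origin sequence
    occurs as a distinct spot at every position.  Replicates aggregate by
    median; missing cells are gapped and counted, and a matrix with more
    than ``max_gap_fraction`` gaps is rejected as unusable.
    """
    if "position" not in screen.data.columns:
        raise ValueError("substitution screen requires a 'position' column")
    df = screen.data.copy()
    df["position"] = df["position"].astype(int)
    lookup = df.groupby(["sequence", "position"])["intensity"].agg(agg)
    positions = spec.resolved_positions
    grid = pd.DataFrame(
        np.nan, index=list(AA_ROW_ORDER), columns=list(positions), dtype=float
    )
    n_gaps = 0
    for var in generate_substitution_library(spec):
        key = (var.sequence, var.position)
        if key in lookup.index:
            grid.at[var.aa, var.position] = float(lookup.loc[key])
        else:
            n_gaps += 1
    total = grid.size
    if n_gaps / total > max_gap_fraction:
        raise ValueError(
            f"{n_gaps}/{total} cells missing (> {max_gap_fraction:.0%}): unusable matrix"
        )
    return SubstitutionMatrix(spec.origin, grid, n_gaps)


@dataclass(frozen=True)
class EpitopeMotif:
    """Per-position invariance calls and their rendered motif string.

    Invariant positions render as the allowed residues joined by ``/``
    (original residue first); freely substitutable positions render ``x``.
    """

    origin: str
    per_position: tuple[tuple[bool, tuple[str, ...]], ...]
    alpha: float
    tau: int

    @property
    def rendered(self) -> str:
        parts = []
        for invariant, allowed in self.per_position:
            parts.append("/".join(allowed) if invariant else "x")
        return "".join(parts)

    @property
    def invariant_positions(self) -> tuple[int, ...]:
        return tuple(
            i + 1 for i, (inv, _) in enumerate(self.per_position) if inv
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin": self.origin,
                "rendered": self.rendered,
                "alpha": self.alpha,
                "tau": self.tau,
                "positions": [
                    {"position": i + 1, "invariant": inv, "allowed": list(allowed)}
                    for i, (inv, allowed) in enumerate(self.per_position)
                ],
            }
        )


def call_motif(
    matrix: SubstitutionMatrix, alpha: float = 1.0, tau: int = 3
) -> EpitopeMotif:
    """Call invariant positions from a substitution matrix.

    The origin reference intensity is the median over the L origin cells.
    A substitution *retains* binding when its cell intensity is at least
    ``alpha`` times that reference.  A position is *invariant* when at most
    ``tau`` foreign residues retain; its allowed set is the retaining
    residues plus the original.  Calls are invariant under any positive
    rescaling of the whole matrix; lowering ``alpha`` can only add
    retaining residues and raising ``tau`` can only add invariant calls.
    """
    origin_vals = matrix.origin_intensities()
    origin_int = float(np.nanmedian(origin_vals))
    if not np.isfinite(origin_int) or origin_int <= 0:
        raise ValueError("origin intensity is zero or missing: uninterpretable matrix")
    cutoff = alpha * origin_int
    calls = []
    for i, orig_aa in enumerate(matrix.origin):
        pos = i + 1
        col = matrix.grid[pos]
        retaining = [
            aa
            for aa in AA_ROW_ORDER
            if aa != orig_aa and np.isfinite(col.loc[aa]) and col.loc[aa] >= cutoff
        ]
        invariant = len(retaining) <= tau
        allowed = (orig_aa,) + tuple(aa for aa in AA_ROW_ORDER if aa in retaining)
        calls.append((invariant, allowed))
    return EpitopeMotif(matrix.origin, tuple(calls), alpha, tau)
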