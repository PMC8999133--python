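"""Greedy resemblance-ranking library design.

Each peptide is scored as the sum of the current occurrence weights of its
sub-fragments.  The library is built iteratively: select the highest-scoring
peptide, zero the weights of all its sub-fragments (so later selections are
credited only for proteome content not yet covered), rescore, repeat.  The
incremental implementation updates only the peptides affected by each reset
via the column (fragment-to-peptide) view of the incidence matrix; it is
output-identical to rescoring every peptide from scratch each iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peptidome import FragmentIndex, PeptideIncidence, enumerate_subfragments


@dataclass(frozen=True)
class RankedLibrary:
    """Ordered selected peptides with the score each held at selection time.

    ``entries`` are ``(rank, peptide, score)`` with ranks consecutive from
    1 and scores non-increasing: weights only ever decrease, so no later
    selection can out-score an earlier one.
    """

    entries: tuple[tuple[int, str, int], ...]
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ranks = [r for r, _, _ in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be consecutive from 1")
        peps = [p for _, p, _ in self.entries]
        if len(set(peps)) != len(peps):
            raise ValueError("selected peptides must be distinct")
        scores = [s for _, _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("score_at_selection must be non-increasing")

    @property
    def peptides(self) -> list[str]:
        return [p for _, p, _ in self.entries]

    @property
    def scores(self) -> list[int]:
        return [s for _, _, s in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["rank", "peptide", "score"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "RankedLibrary":
        df = pd.read_csv(Path(path), sep="\t")
        entries = tuple(
            (int(r), str(p), int(s))
            for r, p, s in zip(df["rank"], df["peptide"], df["score"])
        )
        return cls(entries)


def score_peptides(incidence: PeptideIncidence, index: FragmentIndex) -> np.ndarray:
    """Total weighted score of every peptide: the incidence row sum under
    the current fragment weights."""
    return np.asarray(incidence.matrix @ index.weights, dtype=np.int64)


def select_next(
    scores: np.ndarray, peptides: Sequence[str], excluded: set[int] | None = None
) -> int:
    """Index of the maximum-score non-excluded peptide.

    Ties are broken by lexicographically smallest sequence so the design is
    deterministic without any random state.
    """
    excluded = excluded or set()
    mask = np.ones(len(scores), dtype=bool)
    for i in excluded:
        mask[i] = False
    if not mask.any():
        raise ValueError("all peptides excluded")
    best = scores[mask].max()
    candidates = np.flatnonzero(mask & (scores == best))
    return int(min(candidates, key=lambda i: peptides[i]))


def reset_selected_fragments(index: FragmentIndex, peptide: str) -> FragmentIndex:
    """Zero the weights of every sub-fragment of ``peptide`` (in place).

    Idempotent; fragments of the peptide outside the index's k-range are
    ignored.
    """
    for frag in enumerate_subfragments(peptide, index.kmin, index.kmax):
        fid = index.ids.get(frag)
        if fid is None:
            raise ValueError(f"fragment {frag!r} not in index")
        index.weights[fid] = 0
    return index


def design_library(
    incidence: PeptideIncidence, index: FragmentIndex, size: int
) -> RankedLibrary:
    """Run the greedy score-select-reset loop for ``size`` iterations.

    The recorded score is the value that justified the selection, i.e. the
    peptide's score before its fragments are zeroed.  Selected peptides are
    never re-selected; once every remaining score is zero further picks
    carry no coverage and a warning is issued.
    """
    n = len(incidence.peptides)
    if size < 1:
        raise ValueError("library size must be >= 1")
    if size > n:
        raise ValueError(f"library size {size} exceeds peptide count {n}")
    weights = index.weights.astype(np.int64).copy()
    scores = np.asarray(incidence.matrix @ weights, dtype=np.int64)
    csc = incidence.matrix.tocsc()
    selected_mask = np.zeros(n, dtype=bool)
    peptides = incidence.peptides
    entries: list[tuple[int, str, int]] = []
    warned_zero = False
    for rank in range(1, size + 1):
        live = ~selected_mask
        best = scores[live].max()
        candidates = np.flatnonzero(live & (scores == best))
        sel = int(min(candidates, key=lambda i: peptides[i]))
        if best == 0 and not warned_zero:
            warnings.warn(
                "remaining selections have zero score: proteome coverage is "
                "exhausted before the requested library size"
            )
            warned_zero = True
        entries.append((rank, peptides[sel], int(best)))
        # reset: zero each still-weighted fragment of the selection and
        # decrement only the peptides that contain it
        row = incidence.members(sel)
        for fid in row:
            w = weights[fid]
            if w:
                weights[fid] = 0
                col = csc.indices[csc.indptr[fid] : csc.indptr[fid + 1]]
                scores[col] -= w
        selected_mask[sel] = True
    params = {
        "size": size,
        "kmin": index.kmin,
        "kmax": index.kmax,
        "weighting": index.weighting,
        "n_peptides": n,
    }
    return RankedLibrary(tuple(entries), params)
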