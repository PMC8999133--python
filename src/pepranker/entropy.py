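"""Peptidome k-mer diversity versus full combinatorics.

The number of theoretically possible k-mers grows as ``M**k`` with alphabet
size M = 20, while the number ``Np(k)`` of distinct k-mers actually present
in a proteome saturates once k exceeds the lengths at which sequences stop
being distinguishable.  The discrete increment ``gain(k) = Np(k) - Np(k-1)``
("entropy gain") peaks at the fragment lengths that carry the most
distinguishing power, which is what makes mid-length fragments the natural
epitope granularity.  No smoothing is applied: k is an integer grid.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd

from .peptidome import ProteinRecord, canonical_segments

ALPHABET_SIZE = 20


def unique_kmer_counts(
    records: Iterable[ProteinRecord], kmax: int, alphabet: frozenset | None = None
) -> list[int]:
    """Exact count of distinct k-mers present in the proteome, per k=1..kmax.

    Non-canonical residues break sequences into canonical segments; k-mers
    never span a break.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    segments = [
        seg for rec in records for seg in canonical_segments(rec.sequence, alphabet)
    ]
    counts = []
    for k in range(1, kmax + 1):
        seen: set[str] = set()
        for seg in segments:
            for i in range(len(seg) - k + 1):
                seen.add(seg[i : i + k])
        counts.append(len(seen))
    return counts


def combinatorial_counts(M: int, kmax: int) -> list[int]:
    """Theoretical k-mer counts ``M**k`` (exact integer arithmetic)."""
    if M < 1:
        raise ValueError("alphabet size must be >= 1")
    return [M**k for k in range(1, kmax + 1)]


def entropy_gain(np_counts: list[int]) -> list[int]:
    """First difference of the diversity curve; gain(1) = Np(1)."""
    return [np_counts[0]] + [b - a for a, b in zip(np_counts, np_counts[1:])]


def diversity_profile(
    records: Iterable[ProteinRecord], kmax: int = 10, M: int = ALPHABET_SIZE
) -> pd.DataFrame:
    """Table of k, observed Np, theoretical N = M**k, and gain."""
    np_counts = unique_kmer_counts(records, kmax)
    return pd.DataFrame(
        {
            "k": range(1, kmax + 1),
            "Np": np_counts,
            "N": combinatorial_counts(M, kmax),
            "gain": entropy_gain(np_counts),
        }
    )
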