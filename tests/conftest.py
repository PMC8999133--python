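"""Shared fixtures: toy proteomes, random proteomes, and the naive greedy
oracle used to cross-check the incremental library design."""

from __future__ import annotations

import numpy as np
import pytest

from pepranker.peptidome import (
    CANONICAL_AA,
    ProteinRecord,
    build_fragment_weights,
    build_incidence,
    enumerate_subfragments,
    slice_unique_peptides,
)

TOY_ALPHABET = frozenset("AB")


@pytest.fixture
def toy_proteome():
    """Single 3-residue protein over a two-letter toy alphabet."""
    return [ProteinRecord("toy", "AAB")]


@pytest.fixture
def toy_pipeline(toy_proteome):
    """(peptides, index, incidence) for the hand-checkable toy proteome."""
    peptides = slice_unique_peptides(toy_proteome, 2, alphabet=TOY_ALPHABET)
    index = build_fragment_weights(
        toy_proteome, 1, 2, peptides=peptides, alphabet=TOY_ALPHABET
    )
    incidence = build_incidence(peptides, index)
    return peptides, index, incidence


def random_proteome(seed: int, n_proteins: int = 20, length: int = 60) -> list[ProteinRecord]:
    rng = np.random.default_rng(seed)
    aa = np.array(list(CANONICAL_AA))
    return [
        ProteinRecord(f"R{i}", "".join(rng.choice(aa, size=length)))
        for i in range(n_proteins)
    ]


def naive_greedy(records, size, length=10, kmin=1, kmax=10):
    """From-scratch greedy oracle: rescore every peptide every iteration.

    Pure-python sets and dicts, no sparse algebra; kept deliberately
    independent of the incremental implementation it checks.
    """
    peptides = list(slice_unique_peptides(records, length))
    index = build_fragment_weights(
        records, kmin, kmax, peptides=slice_unique_peptides(records, length)
    )
    weights = {f: int(w) for f, w in zip(index.fragments, index.weights)}
    members = {p: enumerate_subfragments(p, kmin, kmax) for p in peptides}
    remaining = set(peptides)
    out = []
    for rank in range(1, size + 1):
        scored = [(sum(weights[f] for f in members[p]), p) for p in remaining]
        best_score = max(s for s, _ in scored)
        best_pep = min(p for s, p in scored if s == best_score)
        out.append((rank, best_pep, best_score))
        for f in members[best_pep]:
            weights[f] = 0
        remaining.discard(best_pep)
    return out
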