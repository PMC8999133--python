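"""Proteome ingestion and k-mer indexing.

A proteome is sliced into overlapping fixed-length peptides (default ten
residues, overlap nine), the unique peptide set is enumerated, and every
contiguous sub-fragment of length ``kmin..kmax`` of those peptides is
interned into a :class:`FragmentIndex` carrying an occurrence weight: the
number of (possibly overlapping) positions in the whole proteome at which
the fragment occurs.  The binary peptide-by-fragment membership structure
(:class:`PeptideIncidence`) is the sparse matrix on which library scoring
operates: a peptide's score is the weighted sum over the fragments it
contains.
"""

from __future__ import annotations

import re
import warnings
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy import sparse

#: The twenty canonical amino acids, alphabetical by one-letter code.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL_AA)

_NONCANONICAL_RE = re.compile(f"[^{CANONICAL_AA}]+")

#: Default residue replacement applied before slicing: selenocysteine is
#: read through as cysteine (the two share the reactive-site chemistry).
DEFAULT_REPLACEMENTS: Mapping[str, str] = {"U": "C"}


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence after preprocessing.

    The sequence may still contain non-canonical letters (B, J, O, X, Z)
    that no replacement rule maps; downstream slicing and weighting skip
    any window or occurrence position that touches them.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class PreprocessStats:
    """Bookkeeping from :func:`preprocess_sequences`."""

    n_proteins: int
    n_replacements: int
    n_noncanonical_residues: int
    n_dropped_records: int
    n_stop_chars_stripped: int = 0


@dataclass(frozen=True)
class PeptideSet:
    """Unique fixed-length peptides of a proteome, in first-seen order."""

    peptides: tuple[str, ...]
    length: int
    source_stats: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError("peptide set contains duplicates")
        bad = [p for p in self.peptides if len(p) != self.length]
        if bad:
            raise ValueError(f"{len(bad)} peptides are not length {self.length}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[str]:
        return iter(self.peptides)


class FragmentIndex:
    """Interned k-mer fragments with occurrence weights.

    Fragment ids are dense integers assigned in first-seen order over the
    peptide set; the id order is an implementation detail and never affects
    a ranking result.  ``weights[i]`` is a non-negative integer score for
    fragment ``i`` under the configured weighting scheme:

    ``"occurrence"``
        total count of (possibly overlapping) occurrence positions of the
        fragment across all protein sequences — the default, the literal
        reading of occurrence in the whole proteome;
    ``"membership"``
        number of unique peptides that contain the fragment (the incidence
        column sum), exposed as a pluggable alternative.
    """

    def __init__(
        self,
        fragments: Sequence[str],
        weights: np.ndarray,
        kmin: int,
        kmax: int,
        weighting: str = "occurrence",
    ) -> None:
        if len(fragments) != len(weights):
            raise ValueError("fragments and weights length mismatch")
        if np.any(np.asarray(weights) < 0):
            raise ValueError("fragment weights must be non-negative")
        self.fragments: tuple[str, ...] = tuple(fragments)
        self.ids: dict[str, int] = {f: i for i, f in enumerate(self.fragments)}
        self.weights = np.asarray(weights, dtype=np.int64).copy()
        self.kmin = int(kmin)
        self.kmax = int(kmax)
        self.weighting = weighting

    def __len__(self) -> int:
        return len(self.fragments)

    def __contains__(self, fragment: str) -> bool:
        return fragment in self.ids

    def weight_of(self, fragment: str) -> int:
        return int(self.weights[self.ids[fragment]])

    def copy(self) -> "FragmentIndex":
        out = FragmentIndex.__new__(FragmentIndex)
        out.fragments = self.fragments
        out.ids = self.ids
        out.weights = self.weights.copy()
        out.kmin, out.kmax, out.weighting = self.kmin, self.kmax, self.weighting
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "fragment": self.fragments,
                "k": [len(f) for f in self.fragments],
                "weight": self.weights,
            }
        )


@dataclass(frozen=True)
class PeptideIncidence:
    """Binary peptide-by-fragment membership (the sparse incidence matrix).

    ``matrix`` is CSR with one row per peptide of ``peptides`` and one
    column per fragment id of the index it was built against; entries are
    1 where the fragment is a substring of the peptide.
    """

    peptides: tuple[str, ...]
    matrix: sparse.csr_matrix

    def members(self, row: int) -> np.ndarray:
        """Fragment ids occurring in peptide ``row``."""
        return self.matrix.indices[self.matrix.indptr[row] : self.matrix.indptr[row + 1]]

    def __len__(self) -> int:
        return len(self.peptides)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA into ``(id, sequence)`` pairs.

    ``*`` stop characters are stripped with a warning; wrapped and
    unwrapped line layouts are both accepted.
    """
    records = []
    n_stops = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        stops = seq.count("*")
        if stops:
            n_stops += stops
            seq = seq.replace("*", "")
        records.append((rec.id, seq))
    if n_stops:
        warnings.warn(f"stripped {n_stops} '*' stop characters from FASTA input")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _coerce_record(rec) -> tuple[str, str]:
    if isinstance(rec, ProteinRecord):
        return rec.id, rec.sequence
    if isinstance(rec, tuple):
        return rec
    # Bio.SeqRecord duck-typing
    return rec.id, str(rec.seq)


def preprocess_sequences(
    records: Iterable,
    replacements: Mapping[str, str] | None = None,
) -> tuple[list[ProteinRecord], PreprocessStats]:
    """Apply residue replacements and tally non-canonical content.

    Parameters
    ----------
    records
        ``(id, sequence)`` pairs, :class:`ProteinRecord` s, or Biopython
        ``SeqRecord`` s.
    replacements
        Residue-to-residue map applied literally; default ``{"U": "C"}``.

    Returns
    -------
    (records, stats)
        Preprocessed records (empty sequences dropped with a warning) and
        counts of replacements, residual non-canonical residues and
        dropped records.
    """
    if replacements is None:
        replacements = DEFAULT_REPLACEMENTS
    items = [_coerce_record(r) for r in records]
    if not items:
        raise ValueError("no input records")
    trans = str.maketrans(dict(replacements))
    out: list[ProteinRecord] = []
    n_repl = 0
    n_noncanon = 0
    n_dropped = 0
    n_stops = 0
    for rid, seq in items:
        seq = seq.upper()
        if "*" in seq:
            n_stops += seq.count("*")
            seq = seq.replace("*", "")
        n_repl += sum(seq.count(src) for src in replacements)
        seq = seq.translate(trans)
        if not seq:
            n_dropped += 1
            warnings.warn(f"protein {rid!r} empty after preprocessing; dropped")
            continue
        n_noncanon += sum(1 for c in seq if c not in CANONICAL_SET)
        out.append(ProteinRecord(rid, seq))
    stats = PreprocessStats(
        n_proteins=len(out),
        n_replacements=n_repl,
        n_noncanonical_residues=n_noncanon,
        n_dropped_records=n_dropped,
        n_stop_chars_stripped=n_stops,
    )
    return out, stats


def canonical_segments(sequence: str, alphabet: frozenset | None = None) -> list[str]:
    """Maximal runs of in-alphabet residues within a sequence.

    ``alphabet=None`` means the 20 canonical residues; pass a custom set
    (e.g. a reduced toy alphabet) to change what counts as admissible.
    """
    if alphabet is None or alphabet is CANONICAL_SET:
        return [s for s in _NONCANONICAL_RE.split(sequence) if s]
    out, cur = [], []
    for c in sequence:
        if c in alphabet:
            cur.append(c)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def slice_unique_peptides(
    records: Iterable[ProteinRecord],
    length: int = 10,
    alphabet: frozenset | None = None,
) -> PeptideSet:
    """Slice every protein into overlapping windows and deduplicate.

    Every window of ``length`` consecutive in-alphabet residues appears
    exactly once in the result (first-seen order).  Windows containing a
    residue outside ``alphabet`` (default: the 20 canonical amino acids)
    are excluded and counted; proteins shorter than ``length`` contribute
    nothing.
    """
    if length < 1:
        raise ValueError("peptide length must be >= 1")
    seen: dict[str, None] = {}
    n_proteins = 0
    n_windows_total = 0
    n_windows_kept = 0
    for rec in records:
        n_proteins += 1
        n_windows_total += max(len(rec.sequence) - length + 1, 0)
        for seg in canonical_segments(rec.sequence, alphabet):
            for i in range(len(seg) - length + 1):
                seen[seg[i : i + length]] = None
                n_windows_kept += 1
    if not seen:
        warnings.warn("no peptides produced (all proteins shorter than window?)")
    stats = {
        "n_proteins": n_proteins,
        "n_windows_total": n_windows_total,
        "n_windows_noncanonical": n_windows_total - n_windows_kept,
        "n_peptides": len(seen),
    }
    return PeptideSet(tuple(seen), length, stats)


def enumerate_subfragments(seq: str, kmin: int = 1, kmax: int = 10) -> set[str]:
    """All distinct contiguous substrings of ``seq`` with length in [kmin, kmax]."""
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if kmin > kmax:
        raise ValueError("kmin must not exceed kmax")
    out: set[str] = set()
    top = min(kmax, len(seq))
    for k in range(kmin, top + 1):
        for i in range(len(seq) - k + 1):
            out.add(seq[i : i + k])
    return out


def build_fragment_weights(
    records: Iterable[ProteinRecord],
    kmin: int = 1,
    kmax: int = 10,
    peptides: PeptideSet | None = None,
    peptide_length: int = 10,
    weighting: str = "occurrence",
    alphabet: frozenset | None = None,
) -> FragmentIndex:
    """Build the fragment universe and its occurrence weights.

    The universe is restricted to sub-fragments of the unique peptide set
    (for windows of length >= kmax this coincides with the sub-fragments
    of the raw proteins except within proteins shorter than the window,
    which contribute nothing, matching the slicing rule).  Occurrence
    weights count every overlapping occurrence position across all protein
    sequences, skipping positions that touch a non-canonical residue.
    """
    records = list(records)
    if peptides is None:
        peptides = slice_unique_peptides(records, peptide_length, alphabet)
    fragments: list[str] = []
    ids: dict[str, int] = {}
    for pep in peptides:
        for k in range(kmin, min(kmax, len(pep)) + 1):
            for i in range(len(pep) - k + 1):
                frag = pep[i : i + k]
                if frag not in ids:
                    ids[frag] = len(fragments)
                    fragments.append(frag)
    weights = np.zeros(len(fragments), dtype=np.int64)
    if weighting == "occurrence":
        for rec in records:
            for seg in canonical_segments(rec.sequence, alphabet):
                for k in range(kmin, min(kmax, len(seg)) + 1):
                    for i in range(len(seg) - k + 1):
                        fid = ids.get(seg[i : i + k])
                        if fid is not None:
                            weights[fid] += 1
    elif weighting == "membership":
        for pep in peptides:
            for frag in enumerate_subfragments(pep, kmin, kmax):
                weights[ids[frag]] += 1
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return FragmentIndex(fragments, weights, kmin, kmax, weighting)


def build_incidence(peptides: PeptideSet, index: FragmentIndex) -> PeptideIncidence:
    """Binary membership of each peptide in the fragment universe.

    Raises if a sub-fragment of a peptide is absent from the index — the
    two structures were then not built over the same proteome.
    """
    indptr = [0]
    indices: list[int] = []
    for pep in peptides:
        frag_ids = []
        for frag in enumerate_subfragments(pep, index.kmin, index.kmax):
            fid = index.ids.get(frag)
            if fid is None:
                raise ValueError(
                    f"fragment {frag!r} of peptide {pep!r} missing from index "
                    "(inconsistent build)"
                )
            frag_ids.append(fid)
        frag_ids.sort()
        indices.extend(frag_ids)
        indptr.append(len(indices))
    matrix = sparse.csr_matrix(
        (
            np.ones(len(indices), dtype=np.int64),
            np.asarray(indices, dtype=np.int64),
            np.asarray(indptr, dtype=np.int64),
        ),
        shape=(len(peptides), len(index)),
    )
    return PeptideIncidence(tuple(peptides), matrix)
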