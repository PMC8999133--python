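# Methods

## Library design model

The design problem is a coverage-weighted greedy selection. Given a
proteome, the unique set of length-10 windows (overlap 9) defines the
candidate peptides; the universe of fragments is every distinct substring
of length 1–10 of those peptides. Fragment weights are occurrence counts:
the number of (possibly overlapping) positions in the whole proteome at
which the fragment occurs. A peptide's score is the sum of the current
weights of its fragments, and each greedy round selects the top-scoring
peptide and permanently zeroes the weights of all its fragments. The
procedure is a weighted variant of greedy set cover; the recorded
per-selection score is taken *before* the reset (it is the value that
justified the selection) and is provably non-increasing in rank because
weights only ever decrease.

Two weighting schemes are implemented behind one switch:

* `occurrence` (default) — total overlapping occurrence positions across
  all protein sequences; the literal reading of "occurrences in the whole
  proteome".
* `membership` — the number of unique peptides containing the fragment,
  i.e. the incidence column sum.

The default is used everywhere; the alternative exists because the two
readings genuinely diverge on repeat-rich sequence and a user comparing
against other implementations may need either.

**Tie-breaking** is lexicographic on the peptide string: deterministic and
seed-free, so a design is reproducible byte-for-byte. When the requested
library size exceeds achievable coverage, selection continues under the
tie rule with every remaining score zero; the design still honours the
requested size but a warning flags that ranks in the zero-score regime
carry no coverage meaning.

**Implementation.** The incidence structure is a scipy CSR matrix
(peptide × fragment, 0/1); scoring is a sparse mat-vec. The greedy loop
keeps a CSC view so that resetting fragment *f* with weight *w* only
decrements the scores of peptides containing *f*. The contract — not the
mechanism — is normative: the incremental loop is asserted identical,
sequence-for-sequence and score-for-score, to a deliberately naive
pure-Python full-rescore oracle on seeded random proteomes. All scores are
int64 integer arithmetic, so there are no floating-point ties.

**Non-canonical residues.** Selenocysteine (U) is replaced by cysteine at
preprocessing (configurable map). The other ambiguity codes (B, J, O, X,
Z) have no defensible substitution, so any peptide window or occurrence
position touching them is excluded and counted rather than guessed at.
Sequences are split into maximal canonical segments and all slicing and
counting runs per segment. The admissible alphabet is a parameter: the
two-letter worked example (`{"AAB"}` with peptide length 2, k ∈ [1, 2])
runs on the alphabet `{A, B}`.

## Diversity curve

`unique_kmer_counts` counts distinct k-mers exactly (hash sets per k;
exact big-integer arithmetic for the theoretical 20^k counts). The
"entropy gain" is the first difference of the observed curve on the
integer k grid — deliberately unsmoothed, and distinct from Shannon
entropy in bits. On any proteome of total length T the observed count at k
is bounded by min(20^k, available positions), and the gain collapses as
the curve saturates; the k at which the gain peaks is the fragment length
with the most distinguishing power.

## Physicochemical descriptors

All descriptors are additive sums of per-residue constants (and hence
permutation-invariant); none is a conformational claim.

* **SQ** — net charge in elementary charges: (#R + #K + #H) − (#D + #E).
  Histidine counts +1 (grouped with the basic residues); no pH-dependent
  fractional charges. Termini are excluded because array peptides are
  surface-coupled; both conventions are fixed rather than silently
  ambiguous.
* **mass** — average residue masses plus one water (18.02 Da, toggleable).
* **SH** — Wimley–White whole-residue hydrophobicity. The interface
  (POPC bilayer) scale is the default, the n-octanol scale selectable.
  Values are stored with the sign flipped relative to the transfer
  free-energy convention so that larger = more hydrophobic (Trp 1.85,
  Phe 1.13 kcal/mol on the interface scale); Asp/Glu are taken charged,
  His neutral.
* **HP** — helix propensity per Pace & Scholtz, kcal/mol relative to
  alanine (0.0); proline is the strongest breaker at 3.16.

Each table is frozen behind a SHA-256 checksum asserted by the test suite,
so a descriptor value can never drift silently between releases.

## Screen analytics and K_D fitting

Replicate spots aggregate by median (robust to scanner speckle; mean
selectable). Intensity ranking reports descending aggregated intensity
with ratio-to-maximum; both are invariant under positive rescaling of the
scanner gain. The "property trace" orders peptides by ascending intensity
and rolling-median smooths their property values (window 101, centered);
it is a descriptive visualisation aid, not an inference.

Titrations use the two-fold dilution design 200, 100, 50, 25, 12.5, 6.25,
3.125, 1.5625 µg/mL. Doses convert to molar units as
nM = (µg/mL) / M_w[Da] × 10⁶ with the antibody molar mass an explicit
parameter (default 145,000 Da, a whole IgG1); 145 µg/mL ↦ 1000 nM.

The fit minimises Σ(I_obs − I_sat·n/(K_D+n))² with
`scipy.optimize.least_squares` (trust-region reflective), positivity
through bounds, initialisation I_sat ← max I_obs and K_D ← median n,
and 10⁻⁸ relative tolerances. Unweighted least squares is the default;
1/I weighting is available. A fit is flagged unreliable when the series is
flat or when K_D exceeds 3× the highest tested concentration — beyond
that the curve is an extrapolation with no curvature support in the data
(standard saturation-binding practice; the factor is configurable).
Binder classification keeps reliable fits with K_D ≤ 1000 nM, sorted
ascending.

## Substitution matrices and motif calls

A full substitution spec over a length-L origin yields L×20 variants —
one array spot per (position, residue) cell, the original residue
included, so the origin sequence is spotted L times and only L×19+1
sequences are distinct. Because of that coincidence, matrix assembly
matches spots by sequence *plus* substituted-position tag. The grid is
20 (alphabetical one-letter order, for bit-exact output) × L; missing
cells are gapped and counted, and a matrix with more than 20% gaps is
rejected as unusable.

The motif call takes the origin reference as the median of the L origin
cells. A cell *retains* binding when its intensity ≥ α × reference; a
position is *invariant* when at most τ foreign residues retain
(default τ = 3 of 19 — the cutoff is a judgement call the underlying
20×L data cannot make by itself, and it is exposed as a parameter). The
rendered motif joins each invariant position's allowed set with `/`
(original residue first) and writes `x` at free positions. Calls are
invariant under global rescaling; lowering α only adds retaining residues
and raising τ only adds invariant calls (both monotonicities are
property-tested).

α defaults to 1.0 — the "equal to or higher than the original signal"
reading of a retained substitution. Under multiplicative noise that exact
threshold is statistically brittle: every retaining cell sits at the same
latent intensity as the origin spots, so about half of them fall below
the origin *median* by noise alone. Round-trip simulations therefore run
at α = 0.8, comfortably below the planted high/low intensity gap and
far outside the 5% noise band; this is the slack any real dataset needs.

Cyclic peptides (e.g. head-to-tail thioether macrocycles mimicking a
disulfide-constrained receptor loop) carry a cyclization descriptor on the
spec and every variant; enumeration and motif calling are purely
positional and identical to the linear case. No ring geometry is modelled.

## Synthetic data

The generators exist so every pipeline is testable without downloads, and
their defaults are the study conditions used throughout the tests and the
acceptance script.

* **Proteomes** — uniform residues over the canonical alphabet with
  planted motif spikes (motif, copies): each copy overwrites a random
  non-overlapping stretch, so the planted occurrence count is a lower
  bound. This emulates the repeat families (zinc-finger linkers,
  low-complexity acidic/proline runs) that dominate occurrence weights in
  a real proteome. It does **not** emulate realistic residue composition,
  homology structure, or protein length distributions — so passing tests
  demonstrate algorithmic correctness, not biological calibration.
* **Screens/titrations** — latent K_D = baseline / fold^(#W+#F) with
  baseline 2000 nM and fold 2 (hydrophobicity-driven affinity), intensity
  = isotherm value × unit-mean lognormal noise (CV 5% default; lognormal
  keeps fluorescence strictly positive). Parameter-recovery studies draw
  K_D log-uniform on 50–5000 nM over the 8-point dilution series.
  Scanner optics, spot morphology and synthesis failures are out of scope.

Every generator threads a single `numpy.random.default_rng(seed)`; no
global random state, same seed ⇒ byte-identical output.

## Problem sizes

The package's own studies run at desk scale: oracle-equivalence over 20
seeded proteomes of 10 proteins × 50 residues (≈820 unique 10-mers,
≈7,000 fragments each), K_D recovery over 200 titrations, motif round
trips over 50 matrices. The full-scale design (10.4 M peptides × 51.5 M
fragments) is supported by the same code path but is a best-effort run:
the incidence matrix at that scale holds ~570 M nonzeros (≈5 GB as int64
CSR plus a CSC copy), so a full 160,000-peptide design needs a large
memory machine and hours, not a laptop. Nothing in the algorithm depends
on scale; outputs at any scale are deterministic.

## Known limitations

* Occurrence weighting is one defensible reading; per-iteration scores on
  a real proteome depend on it, so absolute scores from other
  implementations are only comparable if the weighting matches.
* The Langmuir model assumes monovalent equilibrium binding; avidity
  effects of a bivalent IgG on a dense surface are not modelled and will
  bias apparent K_D low.
* Motif calls are threshold classifications of noisy intensities; τ and α
  move calls at positions near the boundary, and the defaults are
  conventions, not fitted quantities.
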