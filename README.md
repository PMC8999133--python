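# pepranker

Design and analysis toolkit for **resemblance-ranking peptide libraries**:
ordered subsets of a proteome's 10-mer peptides chosen so that each addition
maximally covers proteome k-mer content not yet represented — plus the
downstream analytics for screening such a library on peptide microarrays
against an antibody (intensity ranking, physicochemical trend traces,
dissociation-constant fitting, and substitutional epitope mapping).

It is aimed at groups who synthesise high-density peptide arrays and need a
compact library (say 10⁵ peptides) that is maximally representative of a
peptidome of 10⁷ unique 10-mers, and who then want to go from raw spot
intensities to K_D values and invariant-residue motifs.

## The algorithm

A proteome is sliced into overlapping 10-mers (overlap 9) and deduplicated
into *n* unique peptides. Every contiguous sub-fragment of length
*k* ∈ [1, 10] of those peptides is interned; fragment *m* receives a weight
*W_m* equal to its total (overlapping) occurrence count in the proteome.
With the binary incidence matrix *SP* (peptide × fragment), peptide *i*
scores

&nbsp;&nbsp;&nbsp;&nbsp;*F_i* = Σ_m *SP_im* · *W_m*

The library is built greedily: take the argmax of *F* (ties broken
lexicographically), then **reset** — zero the weights of every sub-fragment
of the selected peptide — and rescore. Each later selection is therefore
credited only for proteome content not yet covered, which makes the
recorded per-selection score non-increasing with rank. The incremental
implementation (fragment→peptide inverted index, touched peptides only) is
bit-identical to full rescoring, and is tested against a naive full-rescore
oracle.

Binding screens are analysed with the one-site Langmuir isotherm
*I_obs = I_sat · n / (K_D + n)*, fitted per peptide over a two-fold
dilution series (200 → 1.5625 µg/mL, converted to nM at a configurable
antibody molar mass, default 145 kDa for an IgG1). Substitution arrays
(20 residues × L positions per origin peptide) are reduced to a 20×L
intensity grid, from which invariant positions and their allowed residue
sets are called into a motif string such as `W/FFxxFWxxxF`.

## Worked example

```python
from pepranker import (FixtureConfig, synth_proteome, slice_unique_peptides,
                       build_fragment_weights, build_incidence, design_library,
                       annotate, synth_titrations, fit_kd)

cfg = FixtureConfig(seed=55, n_proteins=20, length_min=40, length_max=60,
                    motif_spikes=(("IHTGEKPYKC", 15),))
records = synth_proteome(cfg)                       # 20 synthetic proteins
peptides = slice_unique_peptides(records, 10)       # 824 unique 10-mers
index = build_fragment_weights(records, 1, 10, peptides=peptides)  # 7091 fragments
incidence = build_incidence(peptides, index)
library = design_library(incidence, index, 5)
print(library.to_frame().to_string(index=False))
```

```
 rank    peptide  score
    1 IHTGEKPYKC   1235
    2 FAVDRLHEMS    432
    3 TYAGTVWRNQ    190
    4 EPVTVNNASP     76
    5 CPLYFHQKMG     75
```

The planted 15-copy repeat `IHTGEKPYKC` dominates the occurrence weights
and is selected first at score 1235; after its fragments are reset, the
next best peptide covers only 432 units of new content, and the scores
decline monotonically — exactly the behaviour repeated motifs (zinc-finger
linkers, low-complexity runs) produce in a real proteome. Annotation and a
titration fit:

```python
print(annotate(library.peptides)[["peptide", "SQ", "mass", "SH", "HP"]])
series, true_kd = synth_titrations(1, seed=7, noise_cv=0.05)[0]
fit = fit_kd(series)
print(f"true K_D = {true_kd:.1f} nM, fitted K_D = {fit.kd_nM:.1f} nM")
```

```
   peptide  SQ    mass    SH    HP
IHTGEKPYKC   2 1175.37 -3.28  7.97
FAVDRLHEMS   0 1204.38 -2.68  4.01
TYAGTVWRNQ   1 1195.29  0.45  5.20
EPVTVNNASP  -1 1027.10 -4.34 10.40
CPLYFHQKMG   2 1223.48  0.90  7.62

true K_D = 889.5 nM, fitted K_D = 1021.9 nM
```

`SQ` is the summed charge (R/K/H minus D/E), `mass` the average molecular
weight in Da, `SH` the summed Wimley–White whole-residue hydrophobicity and
`HP` the summed helix propensity (both kcal/mol). The fitted K_D lands
within ~15% of truth at 5% multiplicative noise on an 8-point series.

A command-line interface wraps the same pipelines:

```sh
pepranker design --proteome proteome.fasta --size 160000 --out library.tsv
pepranker fit-kd --screens screens/ --windows windows.yaml --out fits.tsv
pepranker submat --screen screen.tsv --origin WFAEFWEENF --out matrix.tsv
```

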