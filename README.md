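# entrapbench

Entrapment-based auditing of false-discovery-rate (FDR) control in tandem
mass spectrometry analysis.

## The problem

Every proteomics search engine reports discoveries — peptides, precursors,
protein groups — together with a claim that the FDR among them is
controlled at some level (say 1%). Whether that claim is *true* is hard to
check: the tools are often closed source, and their internal decoy-based
error control cannot audit itself. The standard external audit is an
**entrapment experiment**: the search database is extended with sequences
known to be absent from the sample, so that every entrapment discovery is a
verifiable false positive. The subtle part is turning entrapment counts
into a valid statement about the false discovery proportion (FDP) — several
estimators circulating in the literature bound the FDP from the wrong side,
or from no side at all.

`entrapbench` implements the construction of entrapment databases and the
four FDP estimators, with their directional guarantees made explicit and
testable:

| estimator | formula | direction |
|---|---|---|
| combined | N_E (1 + 1/r) / (N_T + N_E) | upper bound (in expectation) |
| lower bound | N_E / (N_T + N_E) | lower bound |
| sample | (N_E / r) / N_T | **no valid direction** |
| paired (r = 1) | (N_E + N_{E≥s>T} + 2·N_{E>T≥s}) / (N_T + N_E) | upper bound, tighter than combined |

Here N_T and N_E count original-target and entrapment discoveries at a
given FDR threshold, r is the entrapment-to-target database ratio, s is the
discovery cutoff score, N_{E≥s>T} counts discovered entrapments whose
paired target scored below the cutoff, and N_{E>T≥s} counts those whose
paired target was also discovered but scored lower. A k-matched
generalisation supports r = k entrapments per target, weighting the two
pair-comparison counts by 1/k.

The package also provides:

* deterministic in-silico tryptic digestion (no proline suppression,
  configurable missed cleavages and length window) from FASTA;
* paired shuffled entrapment databases at peptide and protein level for any
  integer r (C-terminal residue fixed, 20+r retry rule, consistent
  peptide swapping across proteins), and foreign-species entrapment
  databases at any ratio;
* reference FDR procedures to audit: target-decoy competition (TDC) with
  exact q-value inversion, the PSM-and-peptide double competition, and
  decoy-derived empirical p-values with Benjamini–Hochberg or Storey
  q-values;
* a calibrated score simulator with known ground truth, used to verify the
  bound direction of every estimator by Monte Carlo.

## Worked example

`entrapbench demo --seed 1` runs a seeded end-to-end analysis: a synthetic
proteome is digested, a paired shuffled entrapment database (r = 1) is
built, scores are simulated over the combined database, TDC assigns
q-values, and the estimators are evaluated:

```
database: 540 target peptides, 540 entrapments, 0 removed
Entrapment FDP estimation
==========================================================
rows: 719   r: 1   k: 1
methods: lower, combined, paired
----------------------------------------------------------
threshold         lower    combined      paired   N_T   N_E
     0.01        0.0076      0.0153      0.0191   260     2
     0.05        0.0212      0.0424      0.0424   323     7
      0.1        0.0658      0.1315      0.0986   341    24
----------------------------------------------------------
```

Reading the 1% row: of the 262 discoveries reported at q ≤ 0.01, 2 are
entrapments, giving a lower bound of 0.76% and a combined upper bound of
1.5% on the FDP; the paired estimate (1.9% here, noisy at these counts)
additionally uses the target-vs-entrapment score comparisons. An FDP bracket
that straddles the 1% threshold means the audit is inconclusive at that
level; a paired (upper-bound) curve below the diagonal is evidence of valid
FDR control, a lower-bound curve above it is evidence of failure.

The same analysis on real search output:

```sh
entrapbench build-db --fasta proteome.fasta --level peptide --r 1 \
    --seed 7 --out-prefix entrap_db
entrapbench estimate --report discoveries.tsv --pairs entrap_db.pairs.tsv \
    --method lower,combined,paired --out fdp_curve.tsv
```

Library users get the same through `EntrapmentModel(table, pairs,
r=1).fit()`, which returns results with per-threshold curves, a
`summary()` table, and discovery-inflation diagnostics.

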