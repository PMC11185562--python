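# Methods

## Entrapment framework

An entrapment experiment augments the original target database 𝒯 with an
entrapment part ℰ𝒯 of known-absent sequences, at effective size ratio
r = |ℰ𝒯|/|𝒯|, and hides the distinction from the analysis tool. At an FDR
threshold the tool reports N_T original-target and N_E entrapment
discoveries. Because entrapment discoveries are certainly false, and false
discoveries are assumed equally likely to land on an original target as on
an entrapment of equal database share (the equal-chance assumption, the
same exchangeability that justifies target-decoy competition), the counts
bound the unobservable false discovery proportion (FDP):

* **combined** `N_E(1 + 1/r)/(N_T + N_E)` — inflates the entrapment count
  by the estimated number of false *original-target* discoveries (N_E/r)
  and is an upper bound on the FDP of the combined discovery list, in
  expectation.
* **lower bound** `N_E/(N_T + N_E)` — counts only the certain falses.
* **sample** `(N_E/r)/N_T` — targets the FDP among original-target
  discoveries only; it typically underestimates but can also overestimate,
  so the package flags it as directionless and reports it only for
  comparison.
* **paired** — with a bijective target↔entrapment pairing (r = 1), each
  discovered entrapment also reports how it compared with its own target:
  `(N_E + N_{E≥s>T} + 2·N_{E>T≥s})/(N_T + N_E)` where s is the cutoff
  score, N_{E≥s>T} counts discovered entrapments whose paired target
  scored below s, and N_{E>T≥s} those whose paired target was discovered
  but outscored. This keeps the upper-bound direction while removing most
  of the combined method's conservatism.

Estimates are capped at 1.0 for reporting (an FDP is a proportion); the
uncapped values are retained in the curve object's `uncapped` field.

### k-matched generalisation

When each target is paired with k entrapments (so r = k), the package uses
the numerator `N_E + (N_{E≥s>T} + 2·N_{E>T≥s})/k`. The 1/k weight is the
natural generalisation: under exchangeability a false target is equally
likely to occupy any rank among its k + 1 group members, so each of the k
pair comparisons carries 1/k of the evidence a single paired comparison
carries. At k = 1 the paired formula is recovered exactly. For a group of
k + 1 null scores with j members above the cutoff, the numerator's
conditional expectation is j — the group's discovery count — so the
estimator is calibrated on null-dominated lists; the Monte-Carlo suite
verifies the expected-upper-bound direction rather than relying on this
sketch.

### Curves, bands, inflation

The estimated FDP is reported as a function of the FDR threshold: at each
threshold t the discovery set is every row with tool q-value ≤ t, and the
paired cutoff s is the minimum score in that set. The default grid is 200
logarithmic points from 1e-4 to the largest reported q-value. Replicate
experiments are summarised with a 95% coverage band, half-width
1.96·σ_n/√n with σ_n the sample standard deviation of the n replicate
estimates — the standard error of the estimated mean; a literal σ_n/n
variant is available via `literal_n=True` for compatibility with the
tighter convention some reports use. The inflation diagnostic compares n1,
the discoveries the tool reports at a nominal threshold (1% by default),
with n2, the discoveries at the largest threshold where the paired
estimate stays within that level, reporting 100·(n1 − n2)/n2.

## Database construction

**Digestion.** Trypsin cleaves after every K and R with no proline
suppression; the C-terminal fragment is kept regardless of its last
residue; N-terminal methionine is never clipped (the audited pipelines
disable clipping, so the database must not introduce it). Peptide-level
databases use 1 missed cleavage and lengths 7–35; protein-level
construction digests with 0 missed cleavages and no length filter so the
fragments concatenate back into the protein. I and L are distinct
characters throughout; peptides are bare sequences (modifications and
charge belong to report parsing).

**Peptide-level shuffled pairing.** Targets are processed in sorted order
under one seeded generator, so results do not depend on input order. Each
target gets up to 20 + r shuffle attempts (C-terminal residue fixed;
optionally also the N-terminal) to collect r entrapments distinct from
*every* original target and every previously accepted entrapment — global
distinctness, so the r = 1 pairing is a bijection. A target that fails
(e.g. a homopolymer, which only has identical permutations) is removed and
recorded with its attempt count; a 7-mer of six identical residues plus
the fixed terminus is removed after exactly 21 attempts at r = 1. Peptides
containing non-canonical residues (B, Z, X, U, O) cannot be meaningfully
permuted or compared and are likewise removed and logged. The retry budget
is read as 20 + r *total* attempts per target (not per entrapment slot);
the build manifest records this reading.

**Protein-level construction.** Every distinct fully-tryptic fragment
across the collection is assigned r entrapment peptides by the same
shuffling rule, with fallbacks that guarantee nothing is dropped: if only
0 < n < r distinct shuffles are found, the remaining r − n are sampled
with replacement from the n; if none are found the entrapment peptide
equals the original. Entrapment protein j concatenates each fragment's
j-th entrapment in original order, so it preserves the original's length
and tryptic boundary structure, and a fragment shared between proteins is
swapped identically everywhere. Shuffling can relocate internal K/R and
thereby create new cleavage sites inside an entrapment peptide; this is
accepted — the entrapment protein still embeds each swap at its original
span, which is the invariant the tests check.

**Foreign entrapment.** Foreign proteomes are digested with the
peptide-level preset, foreign peptides identical to any original target
peptide are excluded, and the remainder is sampled uniformly without
replacement to round(r·|𝒯|) entries (protein level samples whole
proteins). No pairing exists, so downstream estimation refuses the paired
method for foreign databases.

## Reference FDR procedures

TDC ranks competition winners by decreasing score (ties shuffled by seed)
and reports targets among the top K, with K the largest k such that
(D_k + 1)/max(T_k, 1) ≤ α. The q-value inversion assigns each target the
running minimum of that ratio from its rank onward, capped at 1, which
reproduces the rejection set of TDC at every α — a property the suite
checks exhaustively on random tables. PSM-and-peptide performs the double
competition: best PSM per spectrum, max score per peptide (−∞ for
unmatched peptides), then the higher scorer of each target-decoy pair,
with all ties broken by the seeded generator.

Empirical p-values use the literal fraction #{decoys ≥ t}/#decoys, which
can be exactly 0; a `pseudo_count` option computes
(1 + #{decoys ≥ t})/(1 + #decoys) for callers who need strictly positive
p-values. BH adjustment delegates to statsmodels. Storey's q-values are
implemented here (no Python equivalent of the R `qvalue` package is used):
π₀(λ) = #{p > λ}/(m(1 − λ)) on the grid λ = 0.05, 0.10, …, 0.95 is passed
through a cubic smoothing spline evaluated at the largest λ, clipped to
(0, 1]; a scalar λ uses the direct estimator. Degenerate p-value
distributions fall back to π₀ = 1 with a warning, which makes the result
coincide with BH.

## Simulator

The simulator operationalises the equal-chance assumption as a generative
model: native peptides (truly present) draw scores from a signal
distribution and yield a score at all with probability `detect_prob`;
absent original targets, every entrapment and every decoy draw i.i.d.
scores from one shared null. Gaussian score families are the default; a
Gumbel option reflects the extreme-value character of search-engine score
nulls — the estimators' guarantees are distribution-free, so any
exchangeable null is a valid test bed. Each database peptide competes
against its own decoy and the winners receive TDC q-values, giving a
discovery table whose true FDP is known exactly at any threshold.

Default study conditions: 1000 native and 4000 absent original targets,
r = 1, signal N(4, 1) vs null N(0, 1), detection probability 0.7, 500
replicates. The signal/noise and detection values are chosen so that a few
hundred discoveries exist at a 1% FDR with a realistic admixture of false
ones; sizes keep a 500-replicate run near ten seconds on one CPU while
holding Monte-Carlo standard errors well below the effects being checked.
`bound_experiment` redraws all null scores each replicate — emulating
freshly drawn entrapment and decoy databases — and evaluates each
directional claim on paired per-replicate differences at two standard
errors: lower ≤ truth, combined ≥ truth, paired ≥ truth, paired ≤
combined, and mean TDC FDP ≤ α.

The double-entrapment configuration (`DOUBLE_ENTRAPMENT_CONFIG`, 500
native vs 25 000 absent, 100 replicates) reproduces the controlled-mixture
regime in which the "original target" database is dominated by known-false
foreign sequences: there the direct estimate — the fraction of foreign or
entrapment discoveries — equals the true FDP, and the paired estimate
agrees with it within two standard errors, validating the estimator
itself. The native-minority ratio (1:50) preserves that regime at desk
scale; at native-majority compositions the paired estimator's deliberate
conservative bias (driven by entrapments of undetected native peptides)
exceeds the shrinking Monte-Carlo error, so exact agreement is not
expected and not claimed.

## What the simulator does not capture

Scores are exchangeable by construction; real searches violate this
through homologous/neighbouring peptides with similar spectra, shared
peaks, and rescoring that peeks at labels. Passing bound-direction checks
here therefore validates the estimators *given their assumptions*, not the
assumptions themselves on any particular real dataset. Spectrum-level
structure (peaks, m/z, chromatograms), engine-specific score calibration,
and protein inference beyond the group-labeling rule are out of scope.

## Numerical and design choices

* Entrapment-target score ties in paired counting are broken by a seeded
  fair coin; TDC ranking ties are shuffled by seed. Identical seeds give
  byte-identical outputs everywhere.
* A paired original target absent from a discovery table scores −∞, which
  classifies its entrapment into the target-below-cutoff bin.
* Protein groups are labeled original if any member lacks the entrapment
  accession prefix (`ENTRAP_`); only all-entrapment groups count as
  entrapment discoveries.
* Duplicate report identifiers collapse to the best row: lowest q-value,
  then highest score.
* The sample estimator raises when N_T = 0 with N_E > 0 (its denominator
  is the original-target count); the curve API records it as NaN there.
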