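# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `platmark`, in the order the pipeline runs.

## Cohort model and marker matrix

A patient carries a RECIST 1.1 best-response label; CR/PR defines the
*sensitive* group and SD/PD the *resistant* group (a total partition — no
patient is unlabeled).  All downstream analyses see only the binary
patients × markers matrix.  A marker is a (gene, event class) pair:

- `mutation` — the patient has ≥1 SNV/indel in the gene whose annotated
  effect is coding-altering.  Annotation terms (missense, nonsense,
  frameshift, stop-gain, splice, in-frame indels, …) are normalized to a
  three-valued effect: `non_synonymous`, `synonymous`, `other`.  Only
  `non_synonymous` counts by default; records with unrecognized annotations
  fall into `other` and are excluded, a deliberately conservative default
  (the `count_effects` parameter widens it).
- `cnv_amp` / `cnv_del` — some copy-number segment listing the gene has
  copy number ≥ 2 × the patient's average ploidy, resp. ≤ 0.5 × ploidy.
  Any overlapping segment suffices; no minimum-overlap rule is imposed
  because gene-level CNV calls upstream already aggregate segment evidence.
  Average ploidy is an input (default 2.0) — the pipeline does not estimate
  it.
- `cnv_any` — OR of the two.

Coordinates are 0-based half-open everywhere internally; VCF positions are
converted on read.  Multi-allelic VCF records are split per ALT.  Records
without a gene symbol are kept (they count toward TMB and spectra) but
cannot contribute to markers.

Direction of CNV events: the copy-number landscape this pipeline was built
around is deletion-dominant, and only GAGE2C has an explicitly documented
direction (loss).  The fixture therefore types GAGE2C as `cnv_del` and the
remaining CNV markers as `cnv_any`; the synthetic emitter writes all CNV
marker events as losses (copy number 0.8 against ploidy 2), which makes
`cnv_del` and `cnv_any` coincide on generated data.  Users with known
per-gene directions should select event classes explicitly.

## Genomic metrics

**TMB** = (# non-synonymous somatic mutations) / target size in Mb.  The
target size is configurable and defaults to 50 Mb, the conventional
whole-exome capture footprint; reported group medians therefore depend on
this denominator and are not treated as exact reproduction targets.

**Microsatellites.**  A tract is a maximal periodic run of period *m* ∈
1..5 whose motif is *primitive* (not a power of a shorter motif) and whose
full-repeat count is ≥ 5 (uniform across motif lengths).  Maximality is
character-wise: the period neither continues to the left of the start nor
past the last full repeat.  Reporting the run head with the primitive motif
makes the output unique — a poly-A run appears once as motif `A`, never as
`AA`, and `ACACAC…` appears once (motif `AC`, not its rotation `CA`).
Runs containing `N` are never part of a tract.  The scanner is validated
against a brute-force oracle that tests every (start, motif-length) pair.

**MSI.**  Published MSI pipelines differ in their instability criterion and
this one is chosen, not inherited: a site is *valid* when tumour and
matched-normal repeat-length read histograms both reach `min_depth` (20)
reads, and *unstable* when the total-variation distance between the two
normalized histograms exceeds `shift_threshold` (0.3).  TV distance is
symmetric (swapping tumour and normal cannot change the call) and equals 1
for disjoint length supports.  MSI score = unstable / valid; zero valid
sites scores 0 with a logged warning rather than an error.  Both thresholds
are configurable.

**CNV burden** = fraction of exons whose *midpoint* lies in an amplified /
deleted segment (thresholds as above).  Midpoint membership avoids
fractional-overlap bookkeeping; exons covered by no segment are neutral, so
amp + del ≤ 1 always.

## Mutational spectra and signature refitting

Substitutions are tallied into the standard 96-channel catalog: six
pyrimidine-reference classes (C>A, C>G, C>T, T>A, T>C, T>G) × 16 flanking
contexts, channel order substitution-major then 5′ A,C,G,T then 3′ A,C,G,T
(the COSMIC v2 layout).  Purine-reference calls are reverse-complemented,
so the spectrum is strand-symmetric by construction.  Indels, contig-edge
positions, `N` contexts, and REF/reference mismatches are skipped and
counted, never fatal.

Exposures solve min‖Aᵀe − b‖₂ with e ≥ 0, where A is the 30 × 96 reference
and b the normalized sample spectrum, via `scipy.optimize.nnls`; e is then
renormalized to sum to 1 and the L2 residual reported.  Refitting against a
fixed reference is the entire scope — no de-novo extraction (NMF) is
offered.  Samples with < 20 SNVs are flagged `low_confidence`: NNLS on tiny
catalogs is noise-dominated.

The packaged reference (`data/signatures_synthetic_v2_layout.tsv`) is a
**synthetic** 30 × 96 row-stochastic matrix in the COSMIC v2 layout
(sparse gamma-distributed profiles; "Signature 1" biased to N[C>T]G,
"Signature 3" near-flat), regenerable by
`scripts/make_signature_reference.py`.  It is a stand-in with the same
interface contract, adequate for validating the machinery; real analyses
should load the actual COSMIC v2 TSV (either orientation is auto-detected).
Known identifiability limit: a near-flat profile fitted from a small
catalog leaks mass to combinations of sparse profiles; recovery is
excellent (mean absolute exposure error < 0.005 at 50k mutations) but
degrades below a few thousand mutations, which the low-confidence flag
signals.

## Statistical tests

**Fisher exact, two-sided (probability-mass definition).**  For a 2×2
table with fixed margins, p = Σ over all tables T with those margins of
P(T), where P is hypergeometric and the sum includes T iff
P(T) ≤ P(observed) × (1 + 1e-7).  The relative tolerance absorbs
floating-point ties between mathematically equal table probabilities; the
pmf is computed in log-space (`lgamma`).  This is the convention of R's
`fisher.test` and reproduces the printed p-values of the tables this
package regenerates (0.019, 0.005, 0.041, 0.003, …) at three decimals.

**Mann–Whitney U, two-sided.**  U from midranks.  For combined n ≤ 20 with
no ties: exact enumeration of the permutation distribution via a rank-sum
dynamic programme, two-sidedness as |U − μ| ≥ |U_obs − μ|.  Otherwise: a
normal approximation with the standard tie correction to the variance and a
0.5 continuity correction toward the mean.  At 8 vs 8 the two paths agree
within 0.02.

No multiple-testing correction is applied anywhere by default (matching the
screening convention this pipeline mirrors); `benjamini_hochberg` is
available for users who want adjusted p-values.  p-values are formatted to
three decimals in reports ("0.000"–"1.000"), full precision internally.

## Screening, classifier evaluation, and combination search

Screening builds the group × positivity 2×2 table per marker and keeps
markers with Fisher p < α (default 0.05), sorted by p then label.

A classifier is a marker set under the **any-positive (OR) rule**: a
patient is test-positive iff at least one member marker is 1.  The OR rule
is the single supported combination rule because it reproduces the
union arithmetic of the published panel tables; an all-positive
(intersection) rule is provided for exploration only.  OR-rule
monotonicity — adding a marker can only raise TP and lower TN, so
sensitivity is non-decreasing and specificity non-increasing in the subset
order — is asserted as a property test on random matrices.

The search enumerates every candidate subset of size 1..`max_size`
(default 3, the published panel-size cap) and returns the complete ranking
by (sensitivity desc, specificity desc, p asc, smaller panel first,
lexicographic labels) — a deterministic order chosen for reproducibility,
since no tie-break convention is inherited.  A guard refuses more than 10⁶
subsets and advises pre-screening.  Sensitivity/specificity are undefined
(NaN, rendered "NA") when their denominator group is empty.

## Synthetic data: what it emulates, and what it does not

`generate_cohort` produces cohorts with *exact* per-group marker counts
(seeded subset draws), emitted as the same file formats the readers
consume; reading the files back reproduces the matrix bit-for-bit.
`generate_snv_catalog` samples channels from a known signature mixture and
places each mutation (with replacement) at a genome position whose
trinucleotide context matches on either strand, so spectrum building must
undo the strand bookkeeping to recover the truth.  `generate_msi_evidence`
gives unstable sites a 3-repeat-unit downward shift (comfortably past the
0.3 TV threshold at depth 50) and stable sites the normal distribution, so
the recovered score estimates the simulated unstable fraction to within
sampling error (±0.03 at 500 sites is asserted).

The **reference fixture** is a deterministic 16-patient cohort (9
sensitive: 3 CR + 6 PR; 7 resistant: 1 SD + 6 PD) over 17 markers.  The
patient-level matrix behind the published tables was never released; the
fixture is ONE completion of the printed marginals, found by constraint
search and frozen.  Its constraint list (34 entries: 17 single-marker
confusion tables plus 17 union tables) is machine-checked by an
independent set-arithmetic verifier in the test suite, and
`scripts/find_fixture.py` re-derives a consistent completion from scratch.
Two published rows are handled specially: one pair row whose printed FP=1
contradicts the union rule (both components have FP=0 individually) is
excluded as a likely typographical duplication of the preceding row, and
one single-marker row printing 100% sensitivity alongside a p-value that
matches an (8,1,2,5) table is taken as 8-of-9 positive.  Both are flagged,
not silently resolved.  Unconstrained cells of the completion are real
degrees of freedom: panels the published tables never evaluated (e.g. other
pairs of CNV markers) may also separate the groups perfectly on the
fixture, which is consistent with — not contradicted by — every published
count.  The fixture's clinical columns (ages, PSA/fPSA baselines, therapy
flags) match the published group medians/ranges and per-group totals,
including the endocrine-therapy association (2/9 vs 7/7, Fisher p = 0.003).

What passing tests on synthetic data do **not** show: performance on real
read-level artifacts (the generators emit clean calls, not alignments),
calibration of the MSI thresholds against a gold-standard MSI panel, or
generalization of any discovered marker panel — the search reports
apparent (in-sample) performance on 16 patients, with no cross-validation,
exactly as the design it reproduces.

## Numerical and engineering choices

- Problem sizes in the default test run are desk-scale: 2 kb scanner
  oracles, 1000-exon burden oracles, 20 × 50k-multinomial recovery
  replicates; the full suite runs in a few seconds on one CPU.
- All randomness flows through `numpy.random.default_rng(seed)` (or
  `random.Random(seed)` in auxiliary scripts); generator outputs are
  byte-identical across runs with the same seed.
- Degenerate inputs: empty spectra and empty sample groups raise; zero
  valid MSI sites and empty VCF bodies do not.  Fisher tables with a zero
  margin give p = 1 (single table in the support).
- TSV is the single tabular interchange format (UTF-8, header row,
  tab-delimited); the SEG reader expects a
  `# coordinates=0-based-half-open` comment declaring the convention.

## Known limitations

- The packaged signature reference is synthetic (see above).
- "Average ploidy" is consumed, not estimated.
- CNV direction defaults (`cnv_any` except GAGE2C) are a documented
  interpretation, not a derivation.
- Confidence intervals for marker effect sizes are out of scope, as is any
  survival analysis.
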