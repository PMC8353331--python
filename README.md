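# platmark

Composite genomic biomarker discovery for platinum-drug response, built for
small labelled cohorts with per-patient somatic call files.

Treatment-selection studies in oncology often face exactly this shape of
data: a handful of patients (here, a 16-patient prostate-cancer cohort
treated with the platinum agent dicycloplatin, profiled by whole-exome
sequencing of cell-free DNA), a RECIST response label per patient
(CR/PR = drug-sensitive, SD/PD = drug-resistant), and somatic SNV/indel and
copy-number calls from a standard upstream pipeline.  The question is
whether any small panel of gene-level events separates the resistant
patients from the sensitive ones well enough to screen candidates before
treatment.  `platmark` implements that analysis end to end, reproducibly:

- **Cohort I/O** — sample-sheet TSV, annotated VCF (SNV/indel with
  `GENE`/`EFFECT` INFO keys), SEG-like copy-number TSV; everything is
  reduced to a binary patients × markers matrix, where a marker is a
  *(gene, event class)* pair: `mutation` (≥1 coding-altering SNV/indel),
  `cnv_amp` (copy number ≥ 2 × average ploidy), `cnv_del` (≤ 0.5 × ploidy),
  or `cnv_any`.
- **Genomic metrics** — TMB (non-synonymous mutations per Mb of capture),
  microsatellite discovery (maximal primitive-motif tandem repeats, 1–5 bp
  units, ≥5 repeats) and an MSI score (unstable / valid sites by
  total-variation shift of tumour vs normal repeat-length read histograms),
  and exome amplification/deletion fractions.
- **Mutational signatures** — 96-channel trinucleotide catalogs in the
  pyrimidine convention and exposure refitting against a 30-signature
  reference matrix by non-negative least squares (a synthetic reference in
  the COSMIC v2 layout ships with the package; drop in the real COSMIC v2
  TSV for production use).
- **Statistics** — self-contained two-sided Fisher exact test
  (probability-mass definition: *p* = Σ P(T) over tables with the observed
  margins and P(T) ≤ P(observed)) and two-sided Mann–Whitney *U*
  (exact permutation enumeration for tie-free n ≤ 20, tie- and
  continuity-corrected normal approximation otherwise).
- **Biomarker search** — Fisher screening of differential markers, then
  exhaustive enumeration of OR-rule ("any-positive") panels of up to three
  markers, ranked by sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
  exact *p*, and panel size.
- **Synthetic data** — seeded generators for cohorts with prescribed
  per-group marker counts, signature-mixture SNV catalogs, and
  microsatellite evidence, plus a frozen 16-patient reference fixture whose
  marker matrix is consistent with every published single-marker and
  union confusion count of the study it mirrors.

## Worked example

```python
from platmark import ClassifierSpec, EventClass, Marker, evaluate_classifier
from platmark.synthetic_data import build_reference_fixture

cohort, matrix = build_reference_fixture()   # 9 sensitive + 7 resistant patients
panel = ClassifierSpec(
    frozenset({
        Marker("SP8", EventClass.MUTATION),
        Marker("HNRNPCL1", EventClass.MUTATION),
        Marker("GAGE2C", EventClass.CNV_DEL),
    }),
    positive_class="resistant",
)
c = evaluate_classifier(matrix, panel, cohort)
print(c.tp, c.fn, c.fp, c.tn)            # 7 0 0 9
print(f"{c.sensitivity:.1%} {c.specificity:.1%}")  # 100.0% 100.0%
print(f"p = {c.p_value:.3f}")            # p = 0.000  (exact: 1/11440)
```

Under the OR rule a patient is called resistant when any of the three
events is present; on this cohort the panel flags all 7 resistant patients
(TP=7, FN=0) and none of the 9 sensitive ones (FP=0, TN=9).  The Fisher
*p* is the probability-mass two-sided exact test on that 2×2 table.

The `examples/` directory holds one narrative script per capability
(classifier tables, combination search, signature refitting, metrics/MSI);
each prints the numbers it computes and a line on what they mean.  A thin
CLI wraps the same library calls:

```sh
platmark --outdir data simulate          # write a complete synthetic dataset
platmark --config data/run.yaml screen   # differential markers (Fisher p < alpha)
platmark --config data/run.yaml combos   # ranked OR-rule panels, both classes
```

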