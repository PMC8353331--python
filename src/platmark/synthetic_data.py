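"""Synthetic inputs for every pipeline stage.

Three generators and one frozen fixture:

* :func:`generate_cohort` -- a seeded cohort with prescribed per-group marker
  counts, emitted both in memory and as the on-disk formats the readers
  consume (sample-sheet TSV, per-patient annotated VCF and SEG TSV).
* :func:`build_reference_fixture` -- a deterministic 16-patient cohort (9
  drug-sensitive, 7 drug-resistant) and binary matrix over 17 markers whose
  single-marker and OR-union confusion counts match the published classifier
  tables this package reproduces.  The matrix is ONE consistent completion of
  those printed marginals (patient-level data were never published); any
  consistent completion yields identical downstream tables.  It was found by
  constraint search (see ``scripts/find_fixture.py`` for an audit search) and
  is frozen here; :func:`fixture_constraints`/:func:`verify_fixture` re-check
  every constraint independently.
* :func:`generate_snv_catalog` -- a random reference sequence plus SNVs drawn
  from a known signature mixture, for end-to-end spectrum/refitting checks.
* :func:`generate_msi_evidence` -- microsatellite read-length histograms with
  a prescribed unstable fraction (unstable sites shifted by >= 2 repeat
  units).

All generators are deterministic under a fixed seed, down to file bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import (
    CNVSegment,
    Effect,
    EventClass,
    Marker,
    MarkerMatrix,
    Patient,
    Response,
    SNVRecord,
)
from .genomic_metrics import MicrosatelliteLocus, MSISiteEvidence
from .signatures import BASES, SignatureReference

import pandas as pd

__all__ = [
    "CohortSpec",
    "CatalogSpec",
    "generate_cohort",
    "build_reference_fixture",
    "fixture_constraints",
    "verify_fixture",
    "write_cohort_files",
    "generate_snv_catalog",
    "generate_msi_evidence",
    "FIXTURE_MARKERS",
    "RESISTANCE_CANDIDATES",
    "SUSCEPTIBILITY_CANDIDATES",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# ---------------------------------------------------------------------------
# The frozen fixture cohort
# ---------------------------------------------------------------------------

#: resistant patients (6 PD + 1 SD) then sensitive (3 CR + 6 PR)
_FIXTURE_RESPONSES = {
    "P01": Response.PD, "P02": Response.PD, "P03": Response.PD,
    "P04": Response.PD, "P05": Response.PD, "P06": Response.PD,
    "P07": Response.SD,
    "P08": Response.CR, "P09": Response.CR, "P10": Response.CR,
    "P11": Response.PR, "P12": Response.PR, "P13": Response.PR,
    "P14": Response.PR, "P15": Response.PR, "P16": Response.PR,
}

_R = ["P01", "P02", "P03", "P04", "P05", "P06", "P07"]  # resistant
_S = ["P08", "P09", "P10", "P11", "P12", "P13", "P14", "P15", "P16"]  # sensitive


def _ids(group: Sequence[str], indices: Sequence[int]) -> frozenset:
    return frozenset(group[i - 1] for i in indices)


#: marker -> set of positive patients.  One completion of the published
#: marginals; verified against every constraint by verify_fixture().
FIXTURE_MARKERS: dict = {
    Marker("SP8", EventClass.MUTATION): _ids(_R, [1, 2, 3, 4]),
    Marker("HNRNPCL1", EventClass.MUTATION): _ids(_R, [3, 4, 5, 6]),
    Marker("FRG1", EventClass.MUTATION): _ids(_R, [1, 2, 5, 6]),
    Marker("RBM25", EventClass.MUTATION): _ids(_R, [1, 2, 3, 4, 5]) | _ids(_S, [2]),
    Marker("MUC16", EventClass.MUTATION): _ids(_R, [2, 4, 5, 6, 7]) | _ids(_S, [1]),
    Marker("ASTE1", EventClass.MUTATION): _ids(_R, [1, 2, 3, 4, 7]) | _ids(_S, [1]),
    Marker("TMBIM4", EventClass.MUTATION): _ids(_R, [1, 2, 3, 4, 5, 6]) | _ids(_S, [1, 2]),
    Marker("CTAGE4", EventClass.CNV_ANY): _ids(_R, [1, 2, 4, 5, 6]),
    Marker("GAGE2E", EventClass.CNV_ANY): _ids(_R, [1, 2, 3, 4]),
    Marker("GAGE2C", EventClass.CNV_DEL): _ids(_R, [1, 3, 5, 7]),
    Marker("HORMAD1", EventClass.CNV_ANY): _ids(_R, [1, 2, 3, 5, 6]) | _ids(_S, [1]),
    Marker("VARS", EventClass.CNV_ANY): _ids(_S, [5, 6, 7, 8, 9]),
    Marker("TMSB4Y", EventClass.CNV_ANY): _ids(_S, [1, 2, 3, 4, 5]),
    Marker("MUC22", EventClass.CNV_ANY): _ids(_S, [2, 3, 4, 6, 7]),
    Marker("DPCR1", EventClass.CNV_ANY): _ids(_S, [1, 2, 6, 7, 8]),
    Marker("CDSN", EventClass.CNV_ANY): _ids(_S, [1, 2, 3, 6, 7]),
    Marker("HIST2H2AC", EventClass.CNV_ANY): (
        _ids(_S, [2, 3, 4, 5, 6, 7, 8, 9]) | _ids(_R, [1, 2])
    ),
}

RESISTANCE_CANDIDATES = tuple(list(FIXTURE_MARKERS)[:11])
SUSCEPTIBILITY_CANDIDATES = tuple(list(FIXTURE_MARKERS)[11:])

#: baseline clinical columns for the fixture sample sheet (ages and PSA spans
#: match the published medians/ranges; therapy flags reproduce the published
#: per-group totals, incl. the endocrine-therapy association)
_FIXTURE_CLINICAL = {
    # pid: (age, psa, fpsa, surgery, radio, chemo, endocrine)
    "P01": (51, 2.9, 0.9, 0, 1, 1, 1),
    "P02": (58, 30.0, 5.0, 0, 1, 1, 1),
    "P03": (61, 60.0, 9.0, 1, 0, 1, 1),
    "P04": (63, 79.3, 10.8, 0, 0, 1, 1),
    "P05": (65, 150.0, 15.0, 0, 0, 1, 1),
    "P06": (68, 300.0, 22.0, 0, 0, 0, 1),
    "P07": (72, 800.0, 29.8, 0, 0, 0, 1),
    "P08": (61, 9.9, 0.5, 1, 0, 1, 1),
    "P09": (62, 25.0, 5.0, 0, 0, 1, 1),
    "P10": (64, 50.0, 10.0, 1, 0, 1, 0),
    "P11": (65, 80.0, 12.0, 0, 1, 0, 0),
    "P12": (66, 87.6, 14.0, 0, 0, 0, 0),
    "P13": (68, 120.0, 20.0, 0, 0, 0, 0),
    "P14": (70, 200.0, 30.0, 0, 0, 0, 0),
    "P15": (74, 400.0, 40.0, 0, 0, 0, 0),
    "P16": (79, 775.6, 48.6, 0, 0, 0, 0),
}


def _fixture_cohort() -> list:
    cohort = []
    for pid, response in _FIXTURE_RESPONSES.items():
        age, psa, fpsa, surg, radio, chemo, endo = _FIXTURE_CLINICAL[pid]
        therapy = frozenset(
            name
            for name, flag in zip(
                ("surgery", "radiotherapy", "chemotherapy", "endocrine"),
                (surg, radio, chemo, endo),
            )
            if flag
        )
        cohort.append(
            Patient(
                patient_id=pid,
                response=response,
                prior_therapy=therapy,
                psa_baseline=psa,
                fpsa_baseline=fpsa,
                age=float(age),
            )
        )
    return cohort


def build_reference_fixture() -> tuple:
    """(cohort, MarkerMatrix) for the frozen 16-patient reference fixture."""
    cohort = _fixture_cohort()
    pids = [p.patient_id for p in cohort]
    df = pd.DataFrame(0, index=pids, columns=[str(m) for m in FIXTURE_MARKERS])
    for marker, positives in FIXTURE_MARKERS.items():
        df.loc[sorted(positives), str(marker)] = 1
    df.index.name = "patient_id"
    return cohort, MarkerMatrix(df)


def fixture_constraints() -> list:
    """The frozen constraint list the fixture must satisfy.

    Each entry is ``(markers, positive_class, (tp, fn, fp, tn))``: the
    any-positive union of ``markers`` must yield those confusion counts.
    Singletons restate the single-marker table; the remaining entries are the
    published pairwise/triple union counts (one internally inconsistent pair
    row and the overcounted single-marker row 17 are handled as documented in
    the fixture docstring and methods note).
    """
    M = Marker
    E = EventClass
    res = "resistant"
    sen = "sensitive"
    single = [
        ((M("SP8", E.MUTATION),), res, (4, 3, 0, 9)),
        ((M("HNRNPCL1", E.MUTATION),), res, (4, 3, 0, 9)),
        ((M("FRG1", E.MUTATION),), res, (4, 3, 0, 9)),
        ((M("RBM25", E.MUTATION),), res, (5, 2, 1, 8)),
        ((M("MUC16", E.MUTATION),), res, (5, 2, 1, 8)),
        ((M("ASTE1", E.MUTATION),), res, (5, 2, 1, 8)),
        ((M("TMBIM4", E.MUTATION),), res, (6, 1, 2, 7)),
        ((M("CTAGE4", E.CNV_ANY),), res, (5, 2, 0, 9)),
        ((M("GAGE2E", E.CNV_ANY),), res, (4, 3, 0, 9)),
        ((M("GAGE2C", E.CNV_DEL),), res, (4, 3, 0, 9)),
        ((M("HORMAD1", E.CNV_ANY),), res, (5, 2, 1, 8)),
        ((M("VARS", E.CNV_ANY),), sen, (5, 4, 0, 7)),
        ((M("TMSB4Y", E.CNV_ANY),), sen, (5, 4, 0, 7)),
        ((M("MUC22", E.CNV_ANY),), sen, (5, 4, 0, 7)),
        ((M("DPCR1", E.CNV_ANY),), sen, (5, 4, 0, 7)),
        ((M("CDSN", E.CNV_ANY),), sen, (5, 4, 0, 7)),
        ((M("HIST2H2AC", E.CNV_ANY),), sen, (8, 1, 2, 5)),
    ]
    combos = [
        ((M("SP8", E.MUTATION), M("HNRNPCL1", E.MUTATION)), res, (6, 1, 0, 9)),
        ((M("SP8", E.MUTATION), M("FRG1", E.MUTATION)), res, (6, 1, 0, 9)),
        ((M("FRG1", E.MUTATION), M("HNRNPCL1", E.MUTATION)), res, (6, 1, 0, 9)),
        ((M("SP8", E.MUTATION), M("CTAGE4", E.CNV_ANY)), res, (6, 1, 0, 9)),
        ((M("HNRNPCL1", E.MUTATION), M("CTAGE4", E.CNV_ANY)), res, (6, 1, 0, 9)),
        ((M("SP8", E.MUTATION), M("GAGE2C", E.CNV_DEL)), res, (6, 1, 0, 9)),
        ((M("HNRNPCL1", E.MUTATION), M("ASTE1", E.MUTATION)), res, (7, 0, 1, 8)),
        ((M("FRG1", E.MUTATION), M("ASTE1", E.MUTATION)), res, (7, 0, 1, 8)),
        ((M("ASTE1", E.MUTATION), M("CTAGE4", E.CNV_ANY)), res, (7, 0, 1, 8)),
        ((M("ASTE1", E.MUTATION), M("HORMAD1", E.CNV_ANY)), res, (7, 0, 1, 8)),
        ((M("MUC16", E.MUTATION), M("GAGE2C", E.CNV_DEL)), res, (7, 0, 1, 8)),
        (
            (M("SP8", E.MUTATION), M("HNRNPCL1", E.MUTATION), M("GAGE2C", E.CNV_DEL)),
            res,
            (7, 0, 0, 9),
        ),
        (
            (M("SP8", E.MUTATION), M("FRG1", E.MUTATION), M("GAGE2C", E.CNV_DEL)),
            res,
            (7, 0, 0, 9),
        ),
        ((M("TMSB4Y", E.CNV_ANY), M("HIST2H2AC", E.CNV_ANY)), sen, (9, 0, 2, 5)),
        ((M("CDSN", E.CNV_ANY), M("TMSB4Y", E.CNV_ANY)), sen, (7, 2, 0, 7)),
        ((M("MUC22", E.CNV_ANY), M("TMSB4Y", E.CNV_ANY)), sen, (7, 2, 0, 7)),
        ((M("DPCR1", E.CNV_ANY), M("TMSB4Y", E.CNV_ANY)), sen, (8, 1, 0, 7)),
    ]
    return single + combos


def verify_fixture(matrix: MarkerMatrix, cohort: Sequence[Patient]) -> list:
    """Re-check every frozen constraint directly on the matrix columns.

    Independent of the classifier code path: unions and counts are computed
    with plain set arithmetic here.  Returns a list of violation strings
    (empty when the fixture is consistent).
    """
    resistant = {p.patient_id for p in cohort if p.group == "resistant"}
    sensitive = {p.patient_id for p in cohort if p.group == "sensitive"}
    violations = []
    for markers, positive_class, expected in fixture_constraints():
        union: set = set()
        for m in markers:
            union |= matrix.positives(m)
        pos = resistant if positive_class == "resistant" else sensitive
        neg = sensitive if positive_class == "resistant" else resistant
        got = (
            len(union & pos),
            len(pos - union),
            len(union & neg),
            len(neg - union),
        )
        if got != expected:
            label = "/".join(str(m) for m in markers)
            violations.append(f"{label} ({positive_class}): expected {expected}, got {got}")
    return violations


# ---------------------------------------------------------------------------
# Parameterized cohort generation and file emission
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Prescribes group sizes and per-marker positive counts in each group."""

    n_sensitive: int
    n_resistant: int
    marker_specs: tuple  # of (Marker, count_in_resistant, count_in_sensitive)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensitive <= 0 or self.n_resistant <= 0:
            raise ValueError("both groups must be non-empty")
        for marker, n_res, n_sen in self.marker_specs:
            if not (0 <= n_res <= self.n_resistant) or not (0 <= n_sen <= self.n_sensitive):
                raise ValueError(
                    f"marker {marker}: counts ({n_res}, {n_sen}) exceed group sizes"
                )


def generate_cohort(spec: CohortSpec, outdir: str | Path | None = None) -> tuple:
    """Seeded cohort with exact per-group marker column sums.

    Returns (cohort, MarkerMatrix, paths-dict-or-None).  When ``outdir`` is
    given, writes the sample sheet and per-patient VCF/SEG files; reading
    them back through :mod:`platmark.cohort_io` reproduces the matrix.
    """
    rng = np.random.default_rng(spec.seed)
    resistant_ids = [f"R{i + 1:02d}" for i in range(spec.n_resistant)]
    sensitive_ids = [f"S{i + 1:02d}" for i in range(spec.n_sensitive)]
    cohort = [Patient(pid, Response.PD) for pid in resistant_ids] + [
        Patient(pid, Response.PR) for pid in sensitive_ids
    ]
    pids = [p.patient_id for p in cohort]
    df = pd.DataFrame(0, index=pids, columns=[str(m) for m, _, _ in spec.marker_specs])
    for marker, n_res, n_sen in spec.marker_specs:
        chosen = list(rng.choice(resistant_ids, size=n_res, replace=False)) + list(
            rng.choice(sensitive_ids, size=n_sen, replace=False)
        )
        df.loc[chosen, str(marker)] = 1
    df.index.name = "patient_id"
    matrix = MarkerMatrix(df)
    paths = write_cohort_files(cohort, matrix, outdir) if outdir is not None else None
    return cohort, matrix, paths


#: deterministic synthetic loci for panel genes: consecutive 10 kb blocks
def gene_locus(gene: str, panel: Sequence[str]) -> tuple:
    i = list(panel).index(gene)
    start = 100_000 + i * 10_000
    return "chr1", start, start + 10_000


def write_cohort_files(
    cohort: Sequence[Patient],
    matrix: MarkerMatrix,
    outdir: str | Path,
    ploidy: float = 2.0,
) -> dict:
    """Emit sample sheet, per-patient VCF and SEG files for a marker matrix.

    Mutation markers become one non-synonymous C>T SNV inside the gene's
    synthetic locus; CNV markers become a deleted segment (copy number 0.8
    against average ploidy 2 -- a loss, consistent with the deletion-dominant
    CNV landscape the fixture mirrors); ``cnv_amp`` markers become copy
    number 5 segments.  Files are byte-deterministic given the same inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = sorted({m.gene for m in matrix.markers})

    sheet = outdir / "sample_sheet.tsv"
    rows = ["patient_id\tresponse\tsurgery\tradiotherapy\tchemotherapy\tendocrine"
            "\tpsa_baseline\tfpsa_baseline\tage"]
    for p in cohort:
        flags = "\t".join(
            "1" if t in p.prior_therapy else "0"
            for t in ("surgery", "radiotherapy", "chemotherapy", "endocrine")
        )
        nums = "\t".join(
            "" if v is None else f"{v:g}"
            for v in (p.psa_baseline, p.fpsa_baseline, p.age)
        )
        rows.append(f"{p.patient_id}\t{p.response.value}\t{flags}\t{nums}")
    sheet.write_text("\n".join(rows) + "\n")

    vcf_dir = outdir / "vcf"
    seg_dir = outdir / "seg"
    vcf_dir.mkdir(exist_ok=True)
    seg_dir.mkdir(exist_ok=True)
    for patient in cohort:
        pid = patient.patient_id
        vcf_lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1,length=100000000>",
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        seg_lines = [
            "# coordinates=0-based-half-open",
            "chrom\tstart\tend\tcopy_number\tgenes",
        ]
        for marker in matrix.markers:
            if pid not in matrix.positives(marker):
                continue
            chrom, start, end = gene_locus(marker.gene, panel)
            if marker.event_class is EventClass.MUTATION:
                pos = start + 500  # 1-based emission below
                vcf_lines.append(
                    f"{chrom}\t{pos + 1}\t.\tC\tT\t.\tPASS\t"
                    f"GENE={marker.gene};EFFECT=non_synonymous"
                )
            elif marker.event_class is EventClass.CNV_AMP:
                seg_lines.append(f"{chrom}\t{start}\t{end}\t5.0\t{marker.gene}")
            else:  # cnv_del and cnv_any both emitted as a loss
                seg_lines.append(f"{chrom}\t{start}\t{end}\t0.8\t{marker.gene}")
        (vcf_dir / f"{pid}.vcf").write_text("\n".join(vcf_lines) + "\n")
        (seg_dir / f"{pid}.seg.tsv").write_text("\n".join(seg_lines) + "\n")

    matrix_path = outdir / "marker_matrix.tsv"
    matrix.to_tsv(matrix_path)
    return {
        "sample_sheet": sheet,
        "vcf_dir": vcf_dir,
        "seg_dir": seg_dir,
        "marker_matrix": matrix_path,
        "ploidy": ploidy,
    }


# ---------------------------------------------------------------------------
# Signature-mixture SNV catalogs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CatalogSpec:
    """Truth specification for a simulated SNV catalog."""

    exposures: tuple  # 30 fractions summing to 1
    n_mutations: int
    reference_length: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        exp = np.asarray(self.exposures, dtype=float)
        if (exp < 0).any() or not np.isclose(exp.sum(), 1.0, atol=1e-6):
            raise ValueError("exposures must be non-negative and sum to 1")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")


def generate_snv_catalog(
    spec: CatalogSpec,
    reference: SignatureReference,
    outdir: str | Path | None = None,
    patient_id: str = "SIM",
) -> tuple:
    """(reference dict, SNV records, truth exposures, paths-or-None).

    A uniform-random reference sequence is generated, then mutations are
    sampled channel-wise from the mixture distribution and placed (with
    replacement) at positions whose trinucleotide context matches the sampled
    channel on either strand; purine-strand placements get the
    reverse-complemented ALT so that spectrum building recovers the channel.
    """
    rng = np.random.default_rng(spec.seed)
    seq = "".join(rng.choice(list(BASES), size=spec.reference_length))
    chrom = "chrSIM"

    # index interior positions by (pyrimidine-convention context, strand)
    by_context: dict = {}
    for i in range(1, len(seq) - 1):
        tri = seq[i - 1 : i + 2]
        center = tri[1]
        if center in "CT":
            key = (center, tri[0], tri[2], "+")
        else:
            rc = tri.translate(_COMPLEMENT)[::-1]
            key = (rc[1], rc[0], rc[2], "-")
        by_context.setdefault(key, []).append(i)

    probs = np.asarray(spec.exposures, dtype=float) @ reference.matrix
    probs = probs / probs.sum()
    channel_draws = rng.choice(96, size=spec.n_mutations, p=probs)
    records = []
    for ch in channel_draws:
        sub, five, three = _channel_parts(int(ch))
        ref_base = sub[0]
        alt_base = sub[2]
        candidates = by_context.get((ref_base, five, three, "+"), []) + by_context.get(
            (ref_base, five, three, "-"), []
        )
        if not candidates:
            raise ValueError(
                f"reference of length {spec.reference_length} hosts no "
                f"{five}[{sub}]{three} context; increase reference_length"
            )
        i = int(rng.choice(candidates))
        strand_plus = seq[i] in "CT"
        if strand_plus:
            ref_a, alt_a = seq[i], alt_base
        else:
            ref_a = seq[i]
            alt_a = alt_base.translate(_COMPLEMENT)
        records.append(
            SNVRecord(
                chrom=chrom,
                pos=i + 1,
                ref=ref_a,
                alt=alt_a,
                gene="",
                effect=Effect.NON_SYNONYMOUS,
                patient_id=patient_id,
            )
        )
    truth = np.asarray(spec.exposures, dtype=float)

    paths = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "reference.fa"
        with fasta.open("w") as fh:
            fh.write(f">{chrom}\n")
            for j in range(0, len(seq), 70):
                fh.write(seq[j : j + 70] + "\n")
        vcf = outdir / f"{patient_id}.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={chrom},length={len(seq)}>",
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
            '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
        ]
        for r in sorted(records, key=lambda r: r.pos):
            lines.append(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"EFFECT=non_synonymous"
            )
        vcf.write_text("\n".join(lines) + "\n")
        truth_path = outdir / "truth_exposures.tsv"
        pd.Series(truth, index=reference.names, name="exposure").to_csv(
            truth_path, sep="\t", header=True, index_label="signature"
        )
        paths = {"fasta": fasta, "vcf": vcf, "truth": truth_path}
    return {chrom: seq}, records, truth, paths


def _channel_parts(ch: int) -> tuple:
    from .signatures import SUBSTITUTIONS

    sub = SUBSTITUTIONS[ch // 16]
    five = BASES[(ch % 16) // 4]
    three = BASES[ch % 4]
    return sub, five, three


# ---------------------------------------------------------------------------
# Microsatellite evidence
# ---------------------------------------------------------------------------


def generate_msi_evidence(
    n_sites: int,
    frac_unstable: float,
    depth: int = 50,
    seed: int = 0,
    n_repeats: int = 10,
    min_depth: int = 20,
) -> list:
    """Simulated tumour/normal repeat-length histograms for ``n_sites`` loci.

    The matched normal at every locus concentrates around the reference
    repeat count (60/20/20 split over {n, n-1, n+1}).  A prescribed fraction
    of loci draw their tumour reads from a distribution shifted down by 3
    repeat units (>= 2, comfortably past the instability threshold); the
    rest re-draw from the normal distribution.  Returned evidence is
    unclassified -- run :func:`platmark.genomic_metrics.classify_site_stability`.
    """
    if not (0.0 <= frac_unstable <= 1.0):
        raise ValueError("frac_unstable must be in [0, 1]")
    if depth < min_depth:
        import warnings

        warnings.warn(
            f"depth {depth} < min_depth {min_depth}: all sites will be invalid",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n_unstable = round(n_sites * frac_unstable)
    sites = []
    for i in range(n_sites):
        locus = MicrosatelliteLocus(
            chrom="chrMS",
            start=1000 * i,
            end=1000 * i + n_repeats,
            motif="A",
            n_repeats=n_repeats,
        )
        normal_centre = n_repeats
        tumor_centre = n_repeats - 3 if i < n_unstable else n_repeats
        sites.append(
            MSISiteEvidence(
                locus=locus,
                tumor_lengths=_length_histogram(rng, tumor_centre, depth),
                normal_lengths=_length_histogram(rng, normal_centre, depth),
            )
        )
    return sites


def _length_histogram(rng: np.random.Generator, centre: int, depth: int) -> dict:
    lengths = (centre - 1, centre, centre + 1)
    counts = rng.multinomial(depth, (0.2, 0.6, 0.2))
    return {l: int(c) for l, c in zip(lengths, counts) if c}
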