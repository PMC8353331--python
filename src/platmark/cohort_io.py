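"""Cohort sample sheet, somatic call file readers, and the binary marker matrix.

The pipeline consumes per-patient somatic calls produced upstream (SNV/indel
in annotated VCF, copy-number segments in a SEG-like TSV) together with a
cohort sample sheet carrying the clinical response label for each patient.
Everything downstream -- marker screening, classifier evaluation, combination
search -- operates on the binary patients x markers matrix built here, where a
marker is a (gene, event class) pair:

* ``mutation``  -- at least one coding-altering (non-synonymous) SNV/indel
* ``cnv_amp``   -- a segment containing the gene with copy number >= 2x ploidy
* ``cnv_del``   -- a segment containing the gene with copy number <= 0.5x ploidy
* ``cnv_any``   -- OR of the two CNV classes

Coordinate convention: all intervals are 0-based half-open internally; VCF
positions (1-based) are converted on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Response",
    "Effect",
    "EventClass",
    "Marker",
    "Patient",
    "SNVRecord",
    "CNVSegment",
    "MarkerMatrix",
    "read_sample_sheet",
    "read_snv_calls",
    "read_cnv_segments",
    "build_marker_matrix",
]


class Response(str, enum.Enum):
    """RECIST 1.1 best-response label."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


class Effect(str, enum.Enum):
    NON_SYNONYMOUS = "non_synonymous"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class EventClass(str, enum.Enum):
    MUTATION = "mutation"
    CNV_AMP = "cnv_amp"
    CNV_DEL = "cnv_del"
    CNV_ANY = "cnv_any"


#: annotation terms mapped onto the coding-altering (non-synonymous) class
_NON_SYNONYMOUS_TERMS = {
    "non_synonymous",
    "nonsynonymous",
    "nonsynonymous_snv",
    "missense",
    "missense_variant",
    "nonsense",
    "stopgain",
    "stoploss",
    "frameshift",
    "frameshift_variant",
    "frameshift_insertion",
    "frameshift_deletion",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
    "inframe_insertion",
    "inframe_deletion",
    "splice_site",
    "splicing",
}
_SYNONYMOUS_TERMS = {"synonymous", "synonymous_snv", "synonymous_variant", "silent"}

#: therapy columns recognised in the sample sheet
THERAPY_COLUMNS = ("surgery", "radiotherapy", "chemotherapy", "endocrine")

_TRUTHY = {"1", "yes", "y", "true"}
_FALSY = {"0", "no", "n", "false", ""}


def parse_effect(term: str) -> Effect:
    t = str(term).strip().lower()
    if t in _NON_SYNONYMOUS_TERMS:
        return Effect.NON_SYNONYMOUS
    if t in _SYNONYMOUS_TERMS:
        return Effect.SYNONYMOUS
    return Effect.OTHER


@dataclass(frozen=True)
class Patient:
    """Clinical record; the analysis group is derived from the response."""

    patient_id: str
    response: Response
    prior_therapy: frozenset = frozenset()
    psa_baseline: float | None = None
    fpsa_baseline: float | None = None
    age: float | None = None

    @property
    def group(self) -> str:
        """"sensitive" for CR/PR, "resistant" for SD/PD."""
        return "sensitive" if self.response in (Response.CR, Response.PR) else "resistant"


@dataclass(frozen=True)
class SNVRecord:
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    gene: str
    effect: Effect
    patient_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class CNVSegment:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    copy_number: float
    genes: tuple
    patient_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.copy_number < 0:
            raise ValueError(f"negative copy number {self.copy_number}")


class Marker(tuple):
    """(gene, event_class) pair with a canonical ``GENE:event`` string form."""

    def __new__(cls, gene: str, event_class: EventClass | str):
        return super().__new__(cls, (str(gene), EventClass(event_class)))

    @property
    def gene(self) -> str:
        return self[0]

    @property
    def event_class(self) -> EventClass:
        return self[1]

    def __str__(self) -> str:
        return f"{self.gene}:{self.event_class.value}"

    @classmethod
    def from_string(cls, label: str) -> "Marker":
        gene, _, event = label.rpartition(":")
        if not gene:
            raise ValueError(f"marker label {label!r} is not of the form GENE:event_class")
        return cls(gene, EventClass(event))


@dataclass
class MarkerMatrix:
    """Binary patients x markers matrix backed by a pandas DataFrame.

    Rows are patient ids (order preserved), columns are :class:`Marker`
    labels in ``GENE:event_class`` form; values are 0/1 integers.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValueError("duplicate patient ids in marker matrix")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate marker labels in marker matrix")
        values = self.df.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("marker matrix entries must be 0/1")
        self.df = self.df.astype(int)

    @property
    def patients(self) -> list:
        return list(self.df.index)

    @property
    def markers(self) -> list:
        return [Marker.from_string(c) for c in self.df.columns]

    def column(self, marker: Marker | str) -> pd.Series:
        label = str(marker) if isinstance(marker, Marker) else marker
        if label not in self.df.columns:
            raise KeyError(f"unknown marker {label!r}")
        return self.df[label]

    def positives(self, marker: Marker | str) -> set:
        col = self.column(marker)
        return set(col.index[col == 1])

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "patient_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerMatrix":
        df = pd.read_csv(path, sep="\t", index_col="patient_id")
        for c in df.columns:  # validate labels early
            Marker.from_string(c)
        return cls(df)


def _parse_flag(value, column: str, row_label: str) -> bool:
    s = str(value).strip().lower()
    if s in ("nan", "none"):
        return False
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"sample sheet row {row_label}: cannot parse {column}={value!r} as yes/no")


def read_sample_sheet(path: str | Path) -> list:
    """Read the cohort sample sheet (TSV, one row per patient).

    Required columns: ``patient_id``, ``response`` (CR/PR/SD/PD).  Optional:
    the four therapy flags (``surgery``/``radiotherapy``/``chemotherapy``/
    ``endocrine``, yes-no or 0-1), ``psa_baseline``, ``fpsa_baseline``,
    ``age``.  Row order is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "response"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet is missing required column {col!r}")
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate patient_id {dup!r}")
    patients = []
    for i, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        label = str(row["response"]).strip().upper()
        try:
            response = Response(label)
        except ValueError:
            raise ValueError(
                f"{path}: row {i + 2} (patient {pid!r}): unknown response label {label!r}"
            ) from None
        therapy = frozenset(
            t for t in THERAPY_COLUMNS if t in df.columns and _parse_flag(row[t], t, pid)
        )

        def _num(col):
            if col not in df.columns or pd.isna(row[col]) or str(row[col]).strip() == "":
                return None
            return float(row[col])

        patients.append(
            Patient(
                patient_id=pid,
                response=response,
                prior_therapy=therapy,
                psa_baseline=_num("psa_baseline"),
                fpsa_baseline=_num("fpsa_baseline"),
                age=_num("age"),
            )
        )
    return patients


def split_groups(cohort: Sequence[Patient]) -> tuple:
    """(sensitive, resistant) patient lists, order preserved."""
    sensitive = [p for p in cohort if p.group == "sensitive"]
    resistant = [p for p in cohort if p.group == "resistant"]
    return sensitive, resistant


def read_snv_calls(
    path: str | Path,
    patient_id: str,
    gene_key: str = "GENE",
    effect_key: str = "EFFECT",
) -> list:
    """Read somatic SNV/indel calls from an annotated VCF.

    One :class:`SNVRecord` per ALT allele (multi-allelic sites are split).
    Gene symbol and effect are taken from the INFO keys ``gene_key`` and
    ``effect_key``; records without the gene key are kept with ``gene=""``
    (they are excluded from marker building but still count toward TMB and
    mutation spectra).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    records = []
    n_seen = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"{path}: cannot parse VCF header: {exc}") from exc
    try:
        with vcf:
            for rec in vcf:
                n_seen += 1
                gene = rec.info.get(gene_key, "")
                if isinstance(gene, tuple):
                    gene = gene[0] if gene else ""
                effect_raw = rec.info.get(effect_key, "")
                if isinstance(effect_raw, tuple):
                    effect_raw = effect_raw[0] if effect_raw else ""
                for alt in rec.alts or ():
                    if alt is None or alt == rec.ref:
                        continue
                    records.append(
                        SNVRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gene=str(gene),
                            effect=parse_effect(effect_raw),
                            patient_id=patient_id,
                        )
                    )
    except (ValueError, OSError) as exc:
        raise ValueError(
            f"{path}: malformed VCF record at data line {n_seen + 1}: {exc}"
        ) from exc
    return records


def read_cnv_segments(path: str | Path, patient_id: str) -> list:
    """Read copy-number segments from a SEG-like TSV.

    Columns: ``chrom``, ``start``, ``end``, ``copy_number``, ``genes``
    (semicolon-separated, may be empty).  Coordinates are 0-based half-open,
    declared by a ``# coordinates=0-based-half-open`` comment line which the
    reader skips.  Output is validated and sorted by (chrom, start).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"segment file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "genes": str})
    for col in ("chrom", "start", "end", "copy_number"):
        if col not in df.columns:
            raise ValueError(f"{path}: segment file is missing column {col!r}")
    segments = []
    for i, row in df.iterrows():
        genes_field = row.get("genes", "")
        if pd.isna(genes_field):
            genes_field = ""
        genes = tuple(g for g in str(genes_field).split(";") if g)
        try:
            segments.append(
                CNVSegment(
                    chrom=str(row["chrom"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    copy_number=float(row["copy_number"]),
                    genes=genes,
                    patient_id=patient_id,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def build_marker_matrix(
    cohort: Sequence[Patient],
    snvs: Mapping[str, Iterable[SNVRecord]],
    cnvs: Mapping[str, Iterable[CNVSegment]],
    ploidy: Mapping[str, float] | float = 2.0,
    gene_panel: Sequence[str] = (),
    count_effects: Iterable[Effect] = (Effect.NON_SYNONYMOUS,),
) -> MarkerMatrix:
    """Build the binary marker matrix over ``gene_panel``.

    For every panel gene four columns are produced (mutation, cnv_amp,
    cnv_del, cnv_any).  A gene is amplified in a patient when ANY segment
    listing it has copy number >= 2x that patient's average ploidy, deleted
    when any has copy number <= 0.5x ploidy.  ``ploidy`` is either a single
    default or a per-patient mapping.
    """
    if not gene_panel:
        raise ValueError("gene_panel must not be empty")
    if len(set(gene_panel)) != len(gene_panel):
        raise ValueError("gene_panel contains duplicate symbols")
    count_effects = set(count_effects)

    def _ploidy(pid: str) -> float:
        p = ploidy.get(pid, 2.0) if isinstance(ploidy, Mapping) else float(ploidy)
        if p <= 0:
            raise ValueError(f"ploidy for {pid} must be > 0, got {p}")
        return p

    columns = [str(Marker(g, ec)) for g in gene_panel for ec in EventClass]
    data = np.zeros((len(cohort), len(columns)), dtype=int)
    col_index = {c: j for j, c in enumerate(columns)}
    for i, patient in enumerate(cohort):
        pid = patient.patient_id
        p = _ploidy(pid)
        mutated = {
            r.gene
            for r in snvs.get(pid, ())
            if r.gene and r.effect in count_effects
        }
        amplified: set = set()
        deleted: set = set()
        for seg in cnvs.get(pid, ()):
            if seg.copy_number >= 2.0 * p:
                amplified.update(seg.genes)
            if seg.copy_number <= 0.5 * p:
                deleted.update(seg.genes)
        for g in gene_panel:
            if g in mutated:
                data[i, col_index[str(Marker(g, EventClass.MUTATION))]] = 1
            if g in amplified:
                data[i, col_index[str(Marker(g, EventClass.CNV_AMP))]] = 1
            if g in deleted:
                data[i, col_index[str(Marker(g, EventClass.CNV_DEL))]] = 1
            if g in amplified or g in deleted:
                data[i, col_index[str(Marker(g, EventClass.CNV_ANY))]] = 1
    df = pd.DataFrame(data, index=[p.patient_id for p in cohort], columns=columns)
    df.index.name = "patient_id"
    return MarkerMatrix(df)
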