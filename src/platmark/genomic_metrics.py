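"""Per-sample genomic summary statistics: TMB, microsatellites/MSI, CNV burden.

TMB is the count of somatic non-synonymous (coding-altering) mutations per
megabase of captured target.  Microsatellites are maximal tandem repeats with
a primitive 1-5 bp motif and at least five repeat units; a site is *valid*
when tumour and matched-normal read-length histograms both reach a minimum
depth, and *unstable* when the total-variation distance between the two
normalized repeat-length distributions exceeds a threshold.  The MSI score is
unstable/valid.  CNV burden is the fraction of exons whose midpoint falls in
an amplified (copy number >= 2x average ploidy) or deleted (<= 0.5x ploidy)
segment.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohort_io import CNVSegment, Effect, SNVRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MicrosatelliteLocus",
    "MSISiteEvidence",
    "SampleMetrics",
    "compute_tmb",
    "find_microsatellites",
    "classify_site_stability",
    "msi_score",
    "cnv_burden",
    "write_msi_evidence",
    "read_msi_evidence",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """A maximal tandem-repeat tract (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    motif: str
    n_repeats: int

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.n_repeats:
            raise ValueError("tract span does not equal motif length x repeat count")
        if _smallest_period(self.motif) != len(self.motif):
            raise ValueError(f"motif {self.motif!r} is not primitive")


@dataclass
class MSISiteEvidence:
    """Read-length evidence at one microsatellite locus.

    ``tumor_lengths``/``normal_lengths`` map repeat count -> supporting read
    count.  ``valid``/``unstable`` are set by :func:`classify_site_stability`.
    """

    locus: MicrosatelliteLocus
    tumor_lengths: dict = field(default_factory=dict)
    normal_lengths: dict = field(default_factory=dict)
    valid: bool = False
    unstable: bool = False


@dataclass(frozen=True)
class SampleMetrics:
    patient_id: str
    tmb: float
    msi_score: float
    amp_fraction: float
    del_fraction: float


def compute_tmb(snvs: Iterable[SNVRecord], target_size_mb: float = 50.0) -> float:
    """Non-synonymous mutation count divided by the captured target size (Mb)."""
    if target_size_mb <= 0:
        raise ValueError(f"target_size_mb must be > 0, got {target_size_mb}")
    n = sum(1 for r in snvs if r.effect is Effect.NON_SYNONYMOUS)
    return n / target_size_mb


def _smallest_period(motif: str) -> int:
    for p in range(1, len(motif) + 1):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return p
    return len(motif)  # pragma: no cover


def find_microsatellites(
    sequence: str,
    min_repeats: int = 5,
    max_motif: int = 5,
    chrom: str = "",
) -> list:
    """Scan a nucleotide sequence for microsatellite tracts.

    A tract is reported for every maximal periodic run of period ``m`` in
    1..``max_motif`` whose full-repeat count reaches ``min_repeats`` and whose
    motif is primitive (not itself a repetition of a shorter motif) -- so a
    poly-A run appears once with motif "A", never again as "AA".  Runs
    containing N are never part of a tract.  Output is sorted by start, then
    motif length.
    """
    s = sequence.upper()
    invalid = set(s) - _VALID_BASES
    if invalid:
        raise ValueError(f"invalid characters in sequence: {sorted(invalid)}")
    n = len(s)
    loci = []
    for m in range(1, max_motif + 1):
        i = 0
        while i + m < n:
            if s[i] == s[i + m] and s[i] != "N":
                # extend the periodic run as far as it goes
                t = i
                while t + m + 1 < n and s[t + 1] == s[t + m + 1] and s[t + 1] != "N":
                    t += 1
                run_len = t + m + 1 - i  # chars in the periodic stretch
                reps = run_len // m
                motif = s[i : i + m]
                if reps >= min_repeats and _smallest_period(motif) == m:
                    loci.append(
                        MicrosatelliteLocus(
                            chrom=chrom,
                            start=i,
                            end=i + reps * m,
                            motif=motif,
                            n_repeats=reps,
                        )
                    )
                i = t + 2
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, len(l.motif)))
    return loci


def total_variation_distance(p: Mapping[int, float], q: Mapping[int, float]) -> float:
    """TV distance between two (unnormalized) non-negative histograms."""
    tp = sum(p.values())
    tq = sum(q.values())
    if tp <= 0 or tq <= 0:
        return 1.0
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0) / tp - q.get(k, 0) / tq) for k in keys)


def classify_site_stability(
    evidence: MSISiteEvidence,
    min_depth: int = 20,
    shift_threshold: float = 0.3,
) -> MSISiteEvidence:
    """Set the ``valid``/``unstable`` flags on a site in place (and return it).

    A site is valid when both tumour and normal histograms reach ``min_depth``
    total reads, and unstable when additionally the total-variation distance
    between the normalized repeat-length distributions exceeds
    ``shift_threshold``.
    """
    if any(v < 0 for v in evidence.tumor_lengths.values()) or any(
        v < 0 for v in evidence.normal_lengths.values()
    ):
        raise ValueError("read counts must be non-negative")
    t_depth = sum(evidence.tumor_lengths.values())
    n_depth = sum(evidence.normal_lengths.values())
    evidence.valid = t_depth >= min_depth and n_depth >= min_depth
    evidence.unstable = bool(
        evidence.valid
        and total_variation_distance(evidence.tumor_lengths, evidence.normal_lengths)
        > shift_threshold
    )
    return evidence


def msi_score(sites: Iterable[MSISiteEvidence]) -> float:
    """Fraction of valid microsatellite sites classified unstable."""
    n_valid = 0
    n_unstable = 0
    for site in sites:
        if site.valid:
            n_valid += 1
            if site.unstable:
                n_unstable += 1
    if n_valid == 0:
        logger.warning("MSI score requested with 0 valid sites; returning 0.0")
        return 0.0
    return n_unstable / n_valid


def write_msi_evidence(sites: Iterable[MSISiteEvidence], path) -> None:
    """Write site evidence as TSV: one row per locus, histograms as
    comma-separated ``length:count`` pairs."""
    lines = ["chrom\tstart\tend\tmotif\tn_repeats\ttumor_lengths\tnormal_lengths"]
    for site in sites:
        loc = site.locus
        t = ",".join(f"{k}:{v}" for k, v in sorted(site.tumor_lengths.items()))
        nrm = ",".join(f"{k}:{v}" for k, v in sorted(site.normal_lengths.items()))
        lines.append(
            f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.motif}\t{loc.n_repeats}\t{t}\t{nrm}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def _parse_histogram(text: str) -> dict:
    text = str(text).strip()
    if not text or text == "nan":
        return {}
    out = {}
    for pair in text.split(","):
        k, _, v = pair.partition(":")
        out[int(k)] = int(v)
    return out


def read_msi_evidence(path) -> list:
    """Inverse of :func:`write_msi_evidence`; evidence comes back unclassified."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    sites = []
    for _, row in df.iterrows():
        locus = MicrosatelliteLocus(
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            motif=str(row["motif"]),
            n_repeats=int(row["n_repeats"]),
        )
        sites.append(
            MSISiteEvidence(
                locus=locus,
                tumor_lengths=_parse_histogram(row["tumor_lengths"]),
                normal_lengths=_parse_histogram(row["normal_lengths"]),
            )
        )
    return sites


def cnv_burden(
    exons: Sequence[tuple],
    segments: Iterable[CNVSegment],
    ploidy: float = 2.0,
) -> tuple:
    """(amp_fraction, del_fraction) over exons, by exon-midpoint membership.

    ``exons`` are (chrom, start, end) intervals, 0-based half-open,
    non-overlapping after merge.  An exon counts as amplified/deleted when its
    midpoint lies inside a segment crossing the respective copy-number
    threshold; exons covered by no segment are neutral.
    """
    if not exons:
        raise ValueError("exon list must not be empty")
    if ploidy <= 0:
        raise ValueError(f"ploidy must be > 0, got {ploidy}")
    by_chrom: dict = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    starts: dict = {}
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        starts[chrom] = [s.start for s in segs]
    n_amp = n_del = 0
    for chrom, start, end in exons:
        if start >= end:
            raise ValueError(f"exon start {start} >= end {end}")
        mid = (start + end) / 2.0
        segs = by_chrom.get(chrom)
        if not segs:
            continue
        j = bisect_right(starts[chrom], mid) - 1
        if j < 0:
            continue
        seg = segs[j]
        if not (seg.start <= mid < seg.end):
            continue
        if seg.copy_number >= 2.0 * ploidy:
            n_amp += 1
        elif seg.copy_number <= 0.5 * ploidy:
            n_del += 1
    n = len(exons)
    return n_amp / n, n_del / n
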