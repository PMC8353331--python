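"""Trinucleotide mutation catalogs and mutational-signature refitting.

Single-base substitutions are tallied in the standard 96-channel catalog:
six pyrimidine-reference substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
by 4 x 4 flanking-base contexts.  Substitutions reported on the purine strand
are reverse-complemented into the pyrimidine convention.  Channel order is
substitution-major, then 5' base A,C,G,T, then 3' base A,C,G,T -- the COSMIC
v2 layout.

Per-sample signature exposures are obtained by refitting a fixed reference
catalog of 30 signatures (30 x 96 row-stochastic matrix) to the normalized
sample spectrum with non-negative least squares, then renormalizing the
weights to sum to 1.  No de novo signature extraction is performed.

The packaged reference (``data/signatures_synthetic_v2_layout.tsv``) is a
synthetic stand-in in the COSMIC v2 layout; substitute the real COSMIC v2
TSV via ``load_signature_reference(path)`` for production analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .cohort_io import SNVRecord
from .stats import TestResult, mann_whitney_u

__all__ = [
    "SUBSTITUTIONS",
    "BASES",
    "CHANNELS",
    "channel_index",
    "Spectrum96",
    "SignatureReference",
    "ExposureProfile",
    "build_spectrum",
    "collapse_to_six",
    "fit_exposures",
    "compare_exposures",
    "load_signature_reference",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: low-catalog threshold below which NNLS exposures are flagged low-confidence
LOW_CONFIDENCE_SNVS = 20


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_index(substitution: str, five: str, three: str) -> int:
    """Index of a channel in the fixed 96-channel order."""
    s = SUBSTITUTIONS.index(substitution)
    return s * 16 + BASES.index(five) * 4 + BASES.index(three)


def _channel_labels() -> tuple:
    labels = []
    for sub in SUBSTITUTIONS:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


CHANNELS = _channel_labels()


@dataclass
class Spectrum96:
    """96-channel substitution catalog (counts) for one sample."""

    counts: np.ndarray
    n_total: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError(f"expected 96 channels, got shape {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative channel counts")
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("n_total does not equal the channel sum")


@dataclass
class SignatureReference:
    """Fixed catalog of signature profiles: ``matrix[i]`` is signature i's
    distribution over the 96 channels (rows sum to 1)."""

    names: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 96:
            raise ValueError(f"signature matrix must be n x 96, got {self.matrix.shape}")
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("name count does not match matrix rows")
        if (self.matrix < 0).any():
            raise ValueError("signature profiles must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = self.names[int(np.argmax(np.abs(sums - 1.0)))]
            raise ValueError(f"signature row {bad!r} does not sum to 1")

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ExposureProfile:
    """Per-sample signature mixture weights (non-negative, sum to 1)."""

    patient_id: str
    exposures: np.ndarray
    residual: float
    signature_names: tuple
    low_confidence: bool = False

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if (self.exposures < 0).any():
            raise ValueError("exposures must be non-negative")
        if not np.isclose(self.exposures.sum(), 1.0, atol=1e-6):
            raise ValueError("exposures must sum to 1")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    def as_dict(self) -> dict:
        return dict(zip(self.signature_names, self.exposures))


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a reference accessor.

    Accepts a plain mapping of chrom -> sequence string or a pyfaidx.Fasta
    (any object whose ``[chrom][start:end]`` yields something with ``.seq``
    or that is itself a string).
    """
    contig = reference[chrom]
    piece = contig[start:end]
    seq = getattr(piece, "seq", piece)
    return str(seq).upper()


def build_spectrum(snvs: Iterable[SNVRecord], reference) -> Spectrum96:
    """Tally SNVs into the 96-channel catalog (pyrimidine convention).

    Indels, records at contig edges (no +-1 bp flank), contexts containing N,
    and records whose REF disagrees with the reference sequence are skipped
    and counted in ``n_skipped``, never fatal.
    """
    counts = np.zeros(96, dtype=int)
    n_skipped = 0
    for rec in snvs:
        if not rec.is_snv:
            n_skipped += 1
            continue
        try:
            ctx = _fetch(reference, rec.chrom, rec.pos - 2, rec.pos + 1)
        except (KeyError, IndexError, ValueError):
            n_skipped += 1
            continue
        if len(ctx) != 3 or any(b not in BASES for b in ctx) or ctx[1] != rec.ref.upper():
            n_skipped += 1
            continue
        ref, alt = rec.ref.upper(), rec.alt.upper()
        if alt not in BASES:
            n_skipped += 1
            continue
        if ref in "CT":
            sub = f"{ref}>{alt}"
            five, three = ctx[0], ctx[2]
        else:  # purine strand: reverse-complement the call and its context
            rc = _revcomp(ctx)
            sub = f"{ref.translate(_COMPLEMENT)}>{alt.translate(_COMPLEMENT)}"
            five, three = rc[0], rc[2]
        counts[channel_index(sub, five, three)] += 1
    return Spectrum96(counts=counts, n_total=int(counts.sum()), n_skipped=n_skipped)


def collapse_to_six(spectrum: Spectrum96) -> np.ndarray:
    """Fractions of the six substitution classes (sum to 1)."""
    if spectrum.n_total == 0:
        raise ValueError("cannot collapse an empty spectrum")
    per_class = spectrum.counts.reshape(6, 16).sum(axis=1)
    return per_class / spectrum.n_total


def fit_exposures(
    spectrum: Spectrum96,
    reference: SignatureReference,
    patient_id: str = "",
) -> ExposureProfile:
    """Refit signature exposures to a sample spectrum by NNLS.

    Solves ``min ||A e - b||`` with ``e >= 0`` where A is the 96 x n
    signature matrix and b the normalized spectrum, then renormalizes e to
    sum to 1.  ``residual`` is the Euclidean norm of the NNLS residual.
    Samples with fewer than ``LOW_CONFIDENCE_SNVS`` mutations are flagged
    low-confidence (NNLS on tiny catalogs is noise-dominated).
    """
    if spectrum.n_total == 0:
        raise ValueError("cannot fit exposures to an empty spectrum")
    b = spectrum.counts / spectrum.n_total
    A = reference.matrix.T  # 96 x n
    e, rnorm = nnls(A, b)
    total = e.sum()
    if total <= 0:  # pragma: no cover - signatures are strictly positive
        e = np.full(reference.n_signatures, 1.0 / reference.n_signatures)
    else:
        e = e / total
    return ExposureProfile(
        patient_id=patient_id,
        exposures=e,
        residual=float(rnorm),
        signature_names=reference.names,
        low_confidence=spectrum.n_total < LOW_CONFIDENCE_SNVS,
    )


def compare_exposures(
    group_a: Sequence[ExposureProfile],
    group_b: Sequence[ExposureProfile],
) -> dict:
    """Per-signature two-sided Mann-Whitney comparison of exposures.

    Returns ``{signature name: TestResult}``.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    names = group_a[0].signature_names
    for prof in list(group_a) + list(group_b):
        if prof.signature_names != names:
            raise ValueError("exposure profiles use different signature references")
    results = {}
    for j, name in enumerate(names):
        xs = [p.exposures[j] for p in group_a]
        ys = [p.exposures[j] for p in group_b]
        results[name] = mann_whitney_u(xs, ys)
    return results


def load_signature_reference(path=None) -> SignatureReference:
    """Load a signature reference TSV.

    Accepts either orientation -- signatures x 96 channels or 96 channels x
    signatures -- detected from the header/first column (channel labels such
    as ``A[C>A]A``).  With no path, loads the packaged synthetic reference
    (30 signatures in the COSMIC v2 layout; a stand-in, not COSMIC data).
    """
    if path is None:
        ref_file = resources.files("platmark.data") / "signatures_synthetic_v2_layout.tsv"
        with resources.as_file(ref_file) as p:
            df = pd.read_csv(p, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    channel_set = set(CHANNELS)
    if set(df.index) == channel_set:  # channels x signatures -> transpose
        df = df.T
    elif set(df.columns) != channel_set:
        raise ValueError(
            "signature reference must have the 96 channel labels as its row or column index"
        )
    df = df[list(CHANNELS)]
    return SignatureReference(names=tuple(df.index), matrix=df.to_numpy())
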