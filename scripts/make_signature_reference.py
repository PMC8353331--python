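#!/usr/bin/env python
"""Regenerate the packaged synthetic signature reference.

Writes ``src/platmark/data/signatures_synthetic_v2_layout.tsv``: 30 synthetic
signature profiles over the 96 trinucleotide channels in the COSMIC v2
layout.  The profiles are NOT COSMIC data (which cannot be redistributed
here); they are deterministic sparse random distributions with the same
shape, naming, and row-stochastic contract, adequate for exercising and
validating the refitting machinery.  Signature 1 is biased toward C>T at CpG
-like contexts and Signature 3 is near-flat, mirroring the qualitative
character of their COSMIC namesakes so that worked examples read naturally.

Usage: python scripts/make_signature_reference.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "src" / "platmark" / "data" / "signatures_synthetic_v2_layout.tsv"

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"


def channel_labels():
    return [f"{f}[{s}]{t}" for s in SUBSTITUTIONS for f in BASES for t in BASES]


def main() -> None:
    rng = np.random.default_rng(20150301)
    n_sig = 30
    profiles = rng.gamma(shape=0.15, scale=1.0, size=(n_sig, 96)) + 1e-5

    labels = channel_labels()
    # Signature 1: concentrated on N[C>T]G channels (deamination-like)
    sig1 = np.full(96, 1e-3)
    for i, lab in enumerate(labels):
        if "[C>T]" in lab and lab.endswith("G"):
            sig1[i] = 1.0
    profiles[0] = sig1
    # Signature 3: near-uniform ("flat", HR-deficiency-like)
    profiles[2] = 1.0 + 0.05 * rng.standard_normal(96).clip(-0.9, 0.9)

    profiles /= profiles.sum(axis=1, keepdims=True)
    df = pd.DataFrame(
        profiles,
        index=[f"Signature {i + 1}" for i in range(n_sig)],
        columns=labels,
    )
    df.index.name = "signature"
    df.to_csv(OUT, sep="\t", float_format="%.8g")
    print(f"wrote {OUT} ({OUT.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
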