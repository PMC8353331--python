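"""96-channel spectra, signature refitting, and group comparison."""

import numpy as np
import pytest

from platmark.cohort_io import Effect, SNVRecord
from platmark.signatures import (
    CHANNELS,
    Spectrum96,
    build_spectrum,
    channel_index,
    collapse_to_six,
    compare_exposures,
    fit_exposures,
    load_signature_reference,
)
from platmark.synthetic_data import CatalogSpec, generate_snv_catalog

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def snv(chrom, pos, ref, alt, pid="P01"):
    return SNVRecord(chrom, pos, ref, alt, "", Effect.NON_SYNONYMOUS, pid)


# ---------------------------------------------------------------------------
# spectrum building
# ---------------------------------------------------------------------------


def test_purine_call_reverse_complemented_into_pyrimidine_channel():
    # G>A in context TGC is C>T in context GCA on the opposite strand
    reference = {"chr1": "TGC"}
    spectrum = build_spectrum([snv("chr1", 2, "G", "A")], reference)
    assert spectrum.n_total == 1
    assert spectrum.counts[channel_index("C>T", "G", "A")] == 1


def test_pyrimidine_call_recorded_directly():
    reference = {"chr1": "ACG"}
    spectrum = build_spectrum([snv("chr1", 2, "C", "T")], reference)
    assert spectrum.counts[channel_index("C>T", "A", "G")] == 1


def test_empty_input_gives_zero_spectrum():
    spectrum = build_spectrum([], {"chr1": "ACGT"})
    assert spectrum.n_total == 0 and spectrum.counts.sum() == 0


def test_contig_edge_and_indel_records_skipped_not_fatal():
    reference = {"chr1": "ACGTACGT"}
    records = [
        snv("chr1", 1, "A", "T"),  # no 5' flank
        snv("chr1", 8, "T", "A"),  # no 3' flank
        SNVRecord("chr1", 3, "GT", "G", "", Effect.NON_SYNONYMOUS, "P"),  # indel
        snv("chr1", 2, "C", "A"),  # usable
    ]
    spectrum = build_spectrum(records, reference)
    assert spectrum.n_total == 1
    assert spectrum.n_skipped == 3


def test_spectrum_invariant_under_strand_flip():
    """Re-expressing every call on the opposite strand (reverse-complemented
    genome and alleles) leaves the channel counts unchanged."""
    ref = load_signature_reference()
    exposures = np.zeros(30)
    exposures[[0, 4]] = (0.5, 0.5)
    spec = CatalogSpec(tuple(exposures), n_mutations=300, reference_length=20_000, seed=9)
    genome, records, _, _ = generate_snv_catalog(spec, ref)
    seq = genome["chrSIM"]
    flipped_genome = {"chrSIM": seq.translate(_COMPLEMENT)[::-1]}
    flipped_records = [
        snv(
            "chrSIM",
            len(seq) - r.pos + 1,
            r.ref.translate(_COMPLEMENT),
            r.alt.translate(_COMPLEMENT),
        )
        for r in records
    ]
    s1 = build_spectrum(records, genome)
    s2 = build_spectrum(flipped_records, flipped_genome)
    assert (s1.counts == s2.counts).all()


def test_simulated_catalog_spectrum_near_truth():
    ref = load_signature_reference()
    exposures = np.zeros(30)
    exposures[2] = 1.0
    spec = CatalogSpec(tuple(exposures), n_mutations=5000, reference_length=60_000, seed=4)
    genome, records, truth, _ = generate_snv_catalog(spec, ref)
    spectrum = build_spectrum(records, genome)
    assert spectrum.n_total == 5000
    p_true = truth @ ref.matrix
    p_emp = spectrum.counts / spectrum.n_total
    tv = 0.5 * np.abs(p_true - p_emp).sum()
    # expected TV for a ~96-cell multinomial at n=5000 is ~sqrt(2K/(pi n))/2
    # ~ 0.055; assert within twice that
    assert tv < 0.11


# ---------------------------------------------------------------------------
# six-class collapse
# ---------------------------------------------------------------------------


def test_collapse_pure_ct_spectrum():
    counts = np.zeros(96, dtype=int)
    counts[channel_index("C>T", "A", "A")] = 10
    counts[channel_index("C>T", "G", "C")] = 5
    frac = collapse_to_six(Spectrum96(counts, 15))
    assert frac == pytest.approx([0, 0, 1, 0, 0, 0])


def test_collapse_uniform_spectrum():
    frac = collapse_to_six(Spectrum96(np.ones(96, dtype=int), 96))
    assert frac == pytest.approx(np.full(6, 1 / 6))


def test_collapse_fractions_sum_to_one():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 50, size=96)
    frac = collapse_to_six(Spectrum96(counts, int(counts.sum())))
    assert frac.sum() == pytest.approx(1.0)


def test_collapse_empty_spectrum_errors():
    with pytest.raises(ValueError):
        collapse_to_six(Spectrum96(np.zeros(96, dtype=int), 0))


def test_collapse_agrees_with_direct_snv_tally():
    ref = load_signature_reference()
    exposures = np.zeros(30)
    exposures[[1, 7, 20]] = (0.3, 0.3, 0.4)
    spec = CatalogSpec(tuple(exposures), n_mutations=800, reference_length=30_000, seed=21)
    genome, records, _, _ = generate_snv_catalog(spec, ref)
    spectrum = build_spectrum(records, genome)
    frac = collapse_to_six(spectrum)
    # direct tally: pyrimidine-convention substitution per record
    tally = dict.fromkeys(("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"), 0)
    for r in records:
        ref_b, alt_b = r.ref, r.alt
        if ref_b in "GA":
            ref_b = ref_b.translate(_COMPLEMENT)
            alt_b = alt_b.translate(_COMPLEMENT)
        tally[f"{ref_b}>{alt_b}"] += 1
    direct = np.array([tally[s] for s in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")])
    assert frac == pytest.approx(direct / direct.sum())


# ---------------------------------------------------------------------------
# exposure refitting
# ---------------------------------------------------------------------------


def test_fit_recovers_identity_signature(sig_ref):
    counts = np.round(sig_ref.matrix[2] * 10000).astype(int)
    prof = fit_exposures(Spectrum96(counts, int(counts.sum())), sig_ref)
    assert prof.exposures[2] >= 0.99
    assert prof.exposures.sum() == pytest.approx(1.0)


def test_fit_recovers_two_signature_mixture(sig_ref):
    rng = np.random.default_rng(123)
    truth = np.zeros(30)
    truth[[0, 2]] = (0.6, 0.4)
    counts = rng.multinomial(50_000, truth @ sig_ref.matrix)
    prof = fit_exposures(Spectrum96(counts, 50_000), sig_ref)
    assert abs(prof.exposures[0] - 0.6) < 0.05
    assert abs(prof.exposures[2] - 0.4) < 0.05


def test_fit_parameter_recovery_over_twenty_replicates(sig_ref):
    """Mixtures of <= 4 signatures at 50k mutations: mean absolute exposure
    error below 0.05 in every seeded replicate."""
    errors = []
    for seed in range(20):
        rng = np.random.default_rng(9000 + seed)
        k = int(rng.integers(1, 5))
        idx = rng.choice(30, size=k, replace=False)
        truth = np.zeros(30)
        truth[idx] = rng.dirichlet(np.ones(k))
        counts = rng.multinomial(50_000, truth @ sig_ref.matrix)
        prof = fit_exposures(Spectrum96(counts, 50_000), sig_ref)
        errors.append(np.abs(prof.exposures - truth).mean())
    assert np.mean(errors) < 0.05
    assert max(errors) < 0.05


def test_fit_empty_spectrum_errors(sig_ref):
    with pytest.raises(ValueError):
        fit_exposures(Spectrum96(np.zeros(96, dtype=int), 0), sig_ref)


def test_fit_flags_tiny_catalogs_low_confidence(sig_ref):
    counts = np.zeros(96, dtype=int)
    counts[:10] = 1
    prof = fit_exposures(Spectrum96(counts, 10), sig_ref)
    assert prof.low_confidence
    big = np.round(sig_ref.matrix[0] * 1000).astype(int)
    assert not fit_exposures(Spectrum96(big, int(big.sum())), sig_ref).low_confidence


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def _profile(exposures, sig_ref, pid):
    from platmark.signatures import ExposureProfile

    return ExposureProfile(
        patient_id=pid,
        exposures=exposures,
        residual=0.0,
        signature_names=sig_ref.names,
    )


def test_identical_groups_give_p_one(sig_ref):
    rng = np.random.default_rng(8)
    rows = rng.dirichlet(np.ones(30), size=4)
    a = [_profile(r, sig_ref, f"A{i}") for i, r in enumerate(rows)]
    b = [_profile(r, sig_ref, f"B{i}") for i, r in enumerate(rows)]
    results = compare_exposures(a, b)
    assert all(r.p_value == 1.0 for r in results.values())


def test_shifted_signature_detected_at_9v7(sig_ref):
    rng = np.random.default_rng(15)
    a_rows, b_rows = [], []
    for i in range(9):
        r = rng.dirichlet(np.ones(30))
        r[11] = 0.001 + 0.002 * rng.random()  # signature 12 low in group A
        a_rows.append(r / r.sum())
    for i in range(7):
        r = rng.dirichlet(np.ones(30))
        r[11] = 0.5 + 0.1 * rng.random()  # strongly elevated in group B
        b_rows.append(r / r.sum())
    a = [_profile(r, sig_ref, f"A{i}") for i, r in enumerate(a_rows)]
    b = [_profile(r, sig_ref, f"B{i}") for i, r in enumerate(b_rows)]
    results = compare_exposures(a, b)
    assert results[sig_ref.names[11]].p_value < 0.05


def test_one_vs_one_groups_give_p_one(sig_ref):
    a = [_profile(np.full(30, 1 / 30), sig_ref, "A")]
    r = np.zeros(30)
    r[0] = 1.0
    b = [_profile(r, sig_ref, "B")]
    assert all(res.p_value == 1.0 for res in compare_exposures(a, b).values())


def test_empty_group_errors(sig_ref):
    with pytest.raises(ValueError):
        compare_exposures([], [_profile(np.full(30, 1 / 30), sig_ref, "B")])


# ---------------------------------------------------------------------------
# reference loading
# ---------------------------------------------------------------------------


def test_packaged_reference_contract(sig_ref):
    assert sig_ref.matrix.shape == (30, 96)
    assert sig_ref.names[0] == "Signature 1"
    assert np.allclose(sig_ref.matrix.sum(axis=1), 1.0, atol=1e-6)


def test_reference_loads_in_either_orientation(tmp_path, sig_ref):
    import pandas as pd

    df = pd.DataFrame(sig_ref.matrix, index=list(sig_ref.names), columns=list(CHANNELS))
    direct = tmp_path / "direct.tsv"
    transposed = tmp_path / "transposed.tsv"
    df.to_csv(direct, sep="\t")
    df.T.to_csv(transposed, sep="\t")
    r1 = load_signature_reference(direct)
    r2 = load_signature_reference(transposed)
    assert np.allclose(r1.matrix, r2.matrix)
    assert r1.names == r2.names == sig_ref.names
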