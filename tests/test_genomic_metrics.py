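"""TMB, microsatellite scanning, site stability, MSI score, CNV burden."""

import random

import pytest

from platmark.cohort_io import CNVSegment, Effect, SNVRecord
from platmark.genomic_metrics import (
    MicrosatelliteLocus,
    MSISiteEvidence,
    classify_site_stability,
    cnv_burden,
    compute_tmb,
    find_microsatellites,
    msi_score,
    read_msi_evidence,
    write_msi_evidence,
)


def snv(effect, pos=100):
    return SNVRecord("chr1", pos, "C", "T", "G", effect, "P01")


# ---------------------------------------------------------------------------
# TMB
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n_nonsyn,n_syn,target,expected",
    [(0, 0, 50.0, 0.0), (165, 0, 50.0, 3.3), (60, 40, 50.0, 1.2)],
)
def test_tmb_counts_nonsynonymous_per_mb(n_nonsyn, n_syn, target, expected):
    records = [snv(Effect.NON_SYNONYMOUS, pos=i + 1) for i in range(n_nonsyn)]
    records += [snv(Effect.SYNONYMOUS, pos=10_000 + i) for i in range(n_syn)]
    assert compute_tmb(records, target) == pytest.approx(expected)


def test_tmb_rejects_nonpositive_target():
    with pytest.raises(ValueError):
        compute_tmb([], 0.0)


# ---------------------------------------------------------------------------
# microsatellite scanner
# ---------------------------------------------------------------------------


def microsat_oracle(seq, min_repeats=5, max_motif=5):
    """Brute force: test every (start, motif-length) pair; keep a candidate
    only when it is the full-repeat head of its maximal periodic run."""
    out = set()
    n = len(seq)
    for m in range(1, max_motif + 1):
        for start in range(n - m):
            motif = seq[start : start + m]
            if "N" in motif:
                continue
            # primitive motif only
            if any(
                m % p == 0 and motif == motif[:p] * (m // p) for p in range(1, m)
            ):
                continue
            # run must start here: position start-1 must not continue the period
            if start - 1 >= 0 and seq[start - 1] == seq[start - 1 + m] and seq[start - 1] != "N":
                continue
            # extend periodicity character-wise
            end = start + m
            while end < n and seq[end] == seq[end - m] and seq[end] != "N":
                end += 1
            reps = (end - start) // m
            if reps >= min_repeats:
                out.add((start, start + reps * m, motif, reps))
    return out


def test_poly_a_run_detected():
    loci = find_microsatellites("AAAAA")
    assert len(loci) == 1
    locus = loci[0]
    assert (locus.start, locus.end, locus.motif, locus.n_repeats) == (0, 5, "A", 5)


def test_four_repeats_below_threshold():
    assert find_microsatellites("ACACACAC") == []


def test_dinucleotide_tract_detected_once_with_primitive_motif():
    loci = find_microsatellites("ACACACACACAC")
    assert [(l.motif, l.n_repeats) for l in loci] == [("AC", 6)]


def test_poly_a_not_reported_as_aa():
    loci = find_microsatellites("A" * 12)
    assert [(l.motif, l.n_repeats) for l in loci] == [("A", 12)]


def test_n_runs_never_form_tracts():
    assert find_microsatellites("N" * 30) == []
    assert find_microsatellites("AANAAANAAAANA") == []


def test_invalid_characters_rejected():
    with pytest.raises(ValueError):
        find_microsatellites("ACGTX")


def test_scanner_matches_brute_force_oracle_on_random_sequence():
    rng = random.Random(1234)
    for trial in range(3):
        seq = "".join(rng.choice("ACGTN" if trial == 2 else "ACGT") for _ in range(2000))
        # salt in some genuine repeats so the comparison is not vacuous
        for motif, reps, at in [("A", 8, 100), ("AG", 6, 400), ("CAT", 5, 900), ("GT", 7, 1500)]:
            seq = seq[:at] + motif * reps + seq[at + len(motif) * reps :]
        got = {
            (l.start, l.end, l.motif, l.n_repeats) for l in find_microsatellites(seq)
        }
        assert got == microsat_oracle(seq)


def test_scanner_invariant_under_nonrepetitive_flanks():
    core = "TTTTTTT" + "GACGACGACGACGAC"  # poly-T + (GAC)x5
    flank5, flank3 = "ACGTACGTGCA", "TGCATGACGT"
    base = {(l.motif, l.n_repeats) for l in find_microsatellites(core)}
    flanked = find_microsatellites(flank5 + core + flank3)
    shifted = {(l.motif, l.n_repeats) for l in flanked}
    assert base == shifted
    assert all(l.start >= len(flank5) for l in flanked)


def test_locus_type_enforces_primitivity_and_span():
    with pytest.raises(ValueError):
        MicrosatelliteLocus("c", 0, 10, "AA", 5)  # non-primitive motif
    with pytest.raises(ValueError):
        MicrosatelliteLocus("c", 0, 9, "A", 10)  # span mismatch


# ---------------------------------------------------------------------------
# site stability + MSI score
# ---------------------------------------------------------------------------


def locus(n_repeats=10):
    return MicrosatelliteLocus("chr1", 0, n_repeats, "A", n_repeats)


def test_identical_distributions_stable():
    ev = MSISiteEvidence(locus(), {10: 25, 11: 25}, {10: 25, 11: 25})
    classify_site_stability(ev)
    assert ev.valid and not ev.unstable


def test_disjoint_distributions_unstable():
    ev = MSISiteEvidence(locus(), {7: 50}, {10: 50})
    classify_site_stability(ev)
    assert ev.valid and ev.unstable


def test_low_depth_site_invalid():
    ev = MSISiteEvidence(locus(), {7: 5}, {10: 50})
    classify_site_stability(ev)
    assert not ev.valid and not ev.unstable


def test_stability_symmetric_under_tumor_normal_swap():
    rng = random.Random(2)
    for _ in range(30):
        t = {k: rng.randint(0, 30) for k in range(8, 13)}
        n = {k: rng.randint(0, 30) for k in range(8, 13)}
        a = classify_site_stability(MSISiteEvidence(locus(), dict(t), dict(n)))
        b = classify_site_stability(MSISiteEvidence(locus(), dict(n), dict(t)))
        assert a.unstable == b.unstable and a.valid == b.valid


def test_negative_read_counts_rejected():
    with pytest.raises(ValueError):
        classify_site_stability(MSISiteEvidence(locus(), {10: -1}, {10: 50}))


def test_msi_score_fraction_of_valid_sites():
    sites = []
    for i in range(100):
        ev = MSISiteEvidence(locus(), {7 if i < 7 else 10: 50}, {10: 50})
        sites.append(classify_site_stability(ev))
    assert msi_score(sites) == pytest.approx(0.07)


def test_msi_score_zero_valid_sites_warns_and_returns_zero(caplog):
    ev = classify_site_stability(MSISiteEvidence(locus(), {10: 1}, {10: 1}))
    with caplog.at_level("WARNING"):
        assert msi_score([ev]) == 0.0
    assert "0 valid" in caplog.text


def test_msi_score_all_unstable_is_one():
    sites = [
        classify_site_stability(MSISiteEvidence(locus(), {7: 50}, {10: 50}))
        for _ in range(5)
    ]
    assert msi_score(sites) == 1.0


def test_msi_evidence_tsv_round_trip(tmp_path):
    sites = [
        MSISiteEvidence(locus(), {9: 10, 10: 40}, {10: 50}),
        MSISiteEvidence(
            MicrosatelliteLocus("chr2", 5, 17, "AC", 6), {6: 30}, {6: 28, 7: 2}
        ),
    ]
    path = tmp_path / "ev.tsv"
    write_msi_evidence(sites, path)
    back = read_msi_evidence(path)
    assert len(back) == 2
    for orig, rec in zip(sites, back):
        assert rec.locus == orig.locus
        assert rec.tumor_lengths == orig.tumor_lengths
        assert rec.normal_lengths == orig.normal_lengths


# ---------------------------------------------------------------------------
# CNV burden
# ---------------------------------------------------------------------------


def seg(chrom, start, end, cn):
    return CNVSegment(chrom, start, end, cn, (), "P01")


def test_cnv_burden_simple_amplification():
    exons = [("chr1", i * 100, i * 100 + 50) for i in range(10)]
    segments = [seg("chr1", 0, 180, 5.0)]  # covers midpoints of exons 0 and 1
    amp, dele = cnv_burden(exons, segments, ploidy=2.0)
    assert (amp, dele) == (0.2, 0.0)


def test_cnv_burden_neutral_segments():
    exons = [("chr1", 0, 100), ("chr1", 100, 200)]
    amp, dele = cnv_burden(exons, [seg("chr1", 0, 200, 2.0)], 2.0)
    assert (amp, dele) == (0.0, 0.0)


def test_cnv_burden_empty_exons_errors():
    with pytest.raises(ValueError):
        cnv_burden([], [], 2.0)


def test_cnv_burden_matches_per_exon_oracle():
    rng = random.Random(77)
    exons = []
    pos = 0
    for _ in range(1000):
        pos += rng.randint(1, 50)
        length = rng.randint(1, 40)
        exons.append(("chr1", pos, pos + length))
        pos += length
    segments = []
    cursor = 0
    while cursor < pos:
        length = rng.randint(50, 600)
        if rng.random() < 0.7:
            segments.append(seg("chr1", cursor, cursor + length, rng.choice([0.5, 1.0, 2.0, 4.0, 6.0])))
        cursor += length + rng.randint(0, 100)
    amp, dele = cnv_burden(exons, segments, ploidy=2.0)
    n_amp = n_del = 0
    for chrom, s, e in exons:
        mid = (s + e) / 2
        for g in segments:
            if g.chrom == chrom and g.start <= mid < g.end:
                if g.copy_number >= 4.0:
                    n_amp += 1
                elif g.copy_number <= 1.0:
                    n_del += 1
                break
    assert amp == pytest.approx(n_amp / len(exons))
    assert dele == pytest.approx(n_del / len(exons))
    assert amp + dele <= 1.0


# ---------------------------------------------------------------------------
# hypothesis property: scanner == oracle on arbitrary short sequences
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=120, derandomize=True, deadline=None)
@given(st.text(alphabet="ACGTN", max_size=120))
def test_scanner_matches_oracle_on_arbitrary_sequences(seq):
    got = {(l.start, l.end, l.motif, l.n_repeats) for l in find_microsatellites(seq)}
    assert got == microsat_oracle(seq)
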