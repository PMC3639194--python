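import numpy as np
import pytest

from anther_smallrna.degradome import (
    DegradomeSignature,
    call_cleavage,
    classify_category,
    find_candidate_sites,
    map_degradome,
    normalize_signatures,
    score_duplex,
    tp10m,
    tplot_table,
)
from anther_smallrna.seqs import revcomp

MIRNA = "TGAAGCTGCCAGCATGATCTA"  # 21 nt
SITE = revcomp(MIRNA)


from _duplex_oracle import oracle_score, oracle_sites


# ---------------------------------------------------------------------------
# duplex scoring


def test_perfect_complement_scores_zero():
    aln = score_duplex(MIRNA, SITE)
    assert aln.score == 0.0
    assert set(aln.states) == {"match"}


def test_gu_wobble_position_16():
    # miRNA position 16 is G; replace the paired target C by T -> G:U, x1
    pos = 16
    assert MIRNA[pos - 1] == "G"
    site = list(SITE)
    site[len(MIRNA) - pos] = "T"
    aln = score_duplex(MIRNA, "".join(site))
    assert aln.score == 0.5
    assert aln.states[pos - 1] == "GU"


def test_mismatch_position_5_doubled():
    pos = 5
    site = list(SITE)
    site[len(MIRNA) - pos] = "G"  # miRNA pos 5 is G; G:G is a mismatch
    assert MIRNA[pos - 1] == "G"
    aln = score_duplex(MIRNA, "".join(site))
    assert aln.score == 2.0
    assert aln.states[pos - 1] == "mismatch"


def test_short_segment_rejected():
    with pytest.raises(ValueError):
        score_duplex(MIRNA, SITE[: len(SITE) - 2])


def test_mirna_length_bounds():
    with pytest.raises(ValueError):
        score_duplex("ACGTACGTACGTACGT", SITE)  # 16 nt


def test_gap_variants_match_oracle():
    rng = np.random.default_rng(8)
    for _ in range(30):
        seg_len = len(MIRNA) + int(rng.integers(-1, 2))
        seg = "".join(rng.choice(list("ACGT"), seg_len))
        assert score_duplex(MIRNA, seg).score == pytest.approx(oracle_score(MIRNA, seg))


def test_partner_positions_ungapped():
    aln = score_duplex(MIRNA, SITE, transcript="t", start=101)
    partners = aln.partner_positions()
    # miRNA position 1 pairs the segment 3' end; position L the 5' end
    assert partners[0] == 101 + len(MIRNA) - 1
    assert partners[-1] == 101
    assert aln.cleavage_position(10) == 101 + len(MIRNA) - 10


# ---------------------------------------------------------------------------
# site scanning


def test_single_perfect_site_found():
    transcript = "A" * 50 + SITE + "C" * 40
    sites = find_candidate_sites(MIRNA, {"t1": transcript})
    perfect = [s for s in sites if s.score == 0.0]
    assert len(perfect) == 1
    assert perfect[0].start == 51


def test_no_sites_above_threshold():
    rng = np.random.default_rng(0)
    transcript = "".join(rng.choice(list("ACGT"), 300))
    sites = find_candidate_sites(MIRNA, {"t1": transcript}, max_score=0.0)
    best = oracle_sites(MIRNA, {"t1": transcript}, max_score=0.0)
    assert {(s.transcript, s.start, s.end - s.start + 1, s.score) for s in sites} == best


def test_scan_equals_oracle_small():
    rng = np.random.default_rng(3)
    transcripts = {
        f"t{i}": "".join(rng.choice(list("ACGT"), 200)) for i in range(5)
    }
    transcripts["t_hit"] = "G" * 30 + SITE + "T" * 30
    sites = find_candidate_sites(MIRNA, transcripts, max_score=4.0)
    got = {(s.transcript, s.start, s.end - s.start + 1, s.score) for s in sites}
    assert got == oracle_sites(MIRNA, transcripts, max_score=4.0)


def test_sites_sorted_by_score():
    transcript = "A" * 30 + SITE + "C" * 30 + SITE[:10] + "G" + SITE[11:] + "A" * 20
    sites = find_candidate_sites(MIRNA, {"t1": transcript})
    scores = [s.score for s in sites]
    assert scores == sorted(scores)


# ---------------------------------------------------------------------------
# signatures, normalization, calls


def test_map_single_hit():
    transcript = "A" * 76 + "GTCCGATTGCAAGTCCGATG" + "C" * 40
    read = transcript[76:96]
    sigs = map_degradome([read], {"t1": transcript})
    assert len(sigs) == 1
    assert (sigs[0].transcript, sigs[0].position, sigs[0].hit_number) == ("t1", 77, 1)


def test_map_multi_transcript_hits():
    core = "GTCCGATTGCAAGTCCGATG"
    transcripts = {f"t{i}": ("ACT" * 10) + core + ("GGA" * (5 + i)) for i in range(3)}
    sigs = map_degradome([core], transcripts)
    assert len(sigs) == 3
    assert all(s.hit_number == 3 for s in sigs)


def test_19nt_read_excluded():
    transcript = "A" * 50 + "GTCCGATTGCAAGTCCGAT" + "C" * 30
    assert map_degradome([transcript[50:69]], {"t1": transcript}) == []


def test_tp10m_formula():
    assert tp10m(5, 1_000_000, 0) == pytest.approx(50.0)
    assert tp10m(123, 123, 0) == pytest.approx(10_000_000)


def test_tp10m_zero_denominator():
    with pytest.raises(ValueError):
        tp10m(5, 100, 100)


def test_tp10m_sum_invariant():
    """Sum of TP10M == 1e7 * mapped / (total - structural)."""
    rng = np.random.default_rng(9)
    transcript = "".join(rng.choice(list("ACGT"), 400))
    reads = [transcript[i : i + 20] for i in rng.integers(0, 380, size=200)]
    sigs = map_degradome(reads, {"t1": transcript})
    total, structural = 250, 30
    normalize_signatures(sigs, total, structural)
    mapped_reads = sum(s.raw for s in sigs)
    expect = 1e7 * mapped_reads / (total - structural)
    assert sum(s.tp10m for s in sigs) == pytest.approx(expect, rel=1e-6)


def test_classify_categories():
    raws = {10: 100, 20: 10, 30: 5, 40: 1}
    assert classify_category(100, raws) == 0
    assert classify_category(10, raws) == 2  # median 7.5
    assert classify_category(1, raws) == 4
    shared = {10: 50, 20: 50, 30: 2}
    assert classify_category(50, shared) == 1
    assert classify_category(2, {10: 9, 20: 2, 30: 2, 40: 9}) == 3  # median 5.5


def test_category_scale_invariance():
    raws = {10: 100, 20: 10, 30: 4}
    for scale in (1, 3, 10):
        scaled = {k: v * scale for k, v in raws.items()}
        assert classify_category(100 * scale, scaled) == classify_category(100, raws)
        assert classify_category(10 * scale, scaled) == classify_category(10, raws)


def test_call_requires_coincident_signature():
    transcript = "A" * 50 + SITE + "C" * 40
    sites = find_candidate_sites(MIRNA, {"t1": transcript}, max_score=0.0)
    cleavage = 51 + len(MIRNA) - 10
    sig_ok = [DegradomeSignature("t1", cleavage, 20, raw=30, tp10m=100.0)]
    calls = call_cleavage(sites, sig_ok)
    assert len(calls) == 1
    assert calls[0].cleavage_position == cleavage
    assert calls[0].category == 0
    # signature 3 nt downstream only -> no call
    sig_off = [DegradomeSignature("t1", cleavage + 3, 20, raw=30, tp10m=100.0)]
    assert call_cleavage(sites, sig_off) == []


def test_call_position_11_accepted_canonical_reported():
    transcript = "A" * 50 + SITE + "C" * 40
    sites = find_candidate_sites(MIRNA, {"t1": transcript}, max_score=0.0)
    pos10 = 51 + len(MIRNA) - 10
    sig = [DegradomeSignature("t1", pos10 - 1, 20, raw=12, tp10m=10.0)]  # paired to nt 11
    calls = call_cleavage(sites, sig)
    assert len(calls) == 1
    assert calls[0].matched_position == 11
    assert calls[0].cleavage_position == pos10


def test_two_transcripts_two_calls():
    t1 = "A" * 50 + SITE + "C" * 40
    t2 = "G" * 30 + SITE + "T" * 60
    sites = find_candidate_sites(MIRNA, {"t1": t1, "t2": t2}, max_score=0.0)
    sigs = [
        DegradomeSignature("t1", 51 + len(MIRNA) - 10, 20, raw=5, tp10m=5.0),
        DegradomeSignature("t2", 31 + len(MIRNA) - 10, 20, raw=9, tp10m=9.0),
    ]
    assert len(call_cleavage(sites, sigs)) == 2


def test_tplot_table_flags_call():
    transcript = "A" * 50 + SITE + "C" * 40
    cleavage = 51 + len(MIRNA) - 10
    sigs = [
        DegradomeSignature("t1", 10, 20, raw=3, tp10m=1.0),
        DegradomeSignature("t1", cleavage, 20, raw=40, tp10m=13.0),
    ]
    sites = find_candidate_sites(MIRNA, {"t1": transcript}, max_score=0.0)
    calls = call_cleavage(sites, sigs)
    frame = tplot_table("t1", sigs, calls)
    assert list(frame["position"]) == [10, cleavage]
    flagged = dict(zip(frame["position"], frame["is_cleavage_site"]))
    assert flagged[cleavage] and not flagged[10]


def test_tplot_empty():
    frame = tplot_table("t1", [])
    assert frame.empty
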