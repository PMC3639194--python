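import pytest

from anther_smallrna.conserved_profile import (
    MirnaRef,
    assign_families,
    family_abundance,
    family_name,
    unique_mirna_sharing,
)
from anther_smallrna.errors import ConfigurationError
from anther_smallrna.preprocess import Library, filter_and_collapse

MIR167 = "TGAAGCTGCCAGCATGATCTA"
MIR156 = "TGACAGAAGAGAGTGAGCAC"


def _ref(name, seq, precursor=False):
    return MirnaRef(name, family_name(name), seq, precursor)


def test_family_name_normalization():
    assert family_name("ghr-miR156a") == "miR156"
    assert family_name("ghr-miR167") == "miR167"
    assert family_name("ath-MIR172b") == "miR172"
    assert family_name("osa-let-7c") == "let7"
    assert family_name("trnL") is None


def test_exact_species_match():
    refs = [_ref("ghr-miR167", MIR167)]
    assert assign_families([MIR167], refs) == {MIR167: "miR167"}


def test_three_mismatches_unassigned():
    tag = "AAAAGCTGCCAGCATGATCAA"  # 3 substitutions vs MIR167
    refs = [_ref("ghr-miR167", MIR167)]
    assert assign_families([tag], refs, max_mismatch=2) == {}


def test_two_tier_fallback():
    tier1 = [_ref("ghr-miR167", MIR167)]
    tier2 = [_ref("ath-miR156a", MIR156)]
    out = assign_families([MIR156], tier1, tier2)
    assert out == {MIR156: "miR156"}


def test_tier1_isolated_from_tier2():
    """Tier-1 assignments must not change when tier-2 references change."""
    tier1 = [_ref("ghr-miR167", MIR167)]
    decoy = [_ref("ath-miR9999", MIR167)]  # same sequence, other family
    assert assign_families([MIR167], tier1, [])[MIR167] == "miR167"
    assert assign_families([MIR167], tier1, decoy)[MIR167] == "miR167"


def test_precursor_substring_match():
    precursor = "GGG" + MIR167 + "CCCAAATTTGGGCCCAAATTT"
    refs = [_ref("ghr-MIR167", precursor, precursor=True)]
    tag = MIR167[2:]  # inside the precursor, shorter than the mature
    assert assign_families([tag], refs) == {tag: "miR167"}


def test_offset_tolerance():
    refs = [_ref("ghr-miR167", MIR167)]
    shifted = MIR167[2:] + "GT"  # 2-nt 5' offset, 2-nt 3' extension
    assert assign_families([shifted], refs) == {shifted: "miR167"}
    too_far = MIR167[3:] + "GTC"
    assert assign_families([too_far], refs) == {}


def test_tie_breaks_lexicographically():
    refs = [_ref("ghr-miR300", MIR167), _ref("ghr-miR200", MIR167)]
    assert assign_families([MIR167], refs)[MIR167] == "miR200"


def test_empty_references_rejected():
    with pytest.raises(ConfigurationError):
        assign_families([MIR167], [], [])


def test_assignment_is_function(pipeline_results):
    assignments = pipeline_results["assignments"]
    assert all(isinstance(f, str) for f in assignments.values())


def test_family_abundance_arithmetic():
    libs = [Library("F1", "WT", "meiosis"), Library("S1", "GMS", "meiosis")]
    seq_a, seq_b = MIR167, MIR156
    table, _ = filter_and_collapse({"F1": [seq_a] * 30 + [seq_b] * 70, "S1": [seq_a] * 40})
    assignments = {seq_a: "miR167", seq_b: "miR156"}
    profiles = {p.family: p for p in family_abundance(assignments, table, libs)}
    assert profiles["miR167"].relative_abundance["WT"] == pytest.approx(0.30)
    assert profiles["miR156"].relative_abundance["WT"] == pytest.approx(0.70)
    # share of (WT + GMS) total for miR167: 30 / (30 + 40)
    assert profiles["miR167"].share_of_total["WT"] == pytest.approx(30 / 70)
    # family absent from a genotype
    assert profiles["miR156"].relative_abundance["GMS"] == 0.0


def test_share_of_total_60_40():
    libs = [Library("F1", "WT", "meiosis"), Library("S1", "GMS", "meiosis")]
    table, _ = filter_and_collapse({"F1": [MIR167] * 60, "S1": [MIR167] * 40})
    profiles = family_abundance({MIR167: "miR167"}, table, libs)
    assert profiles[0].share_of_total["WT"] == pytest.approx(0.60)


def test_planted_family_recovery(dataset, pipeline_results):
    """Every planted conserved miRNA family receives >= its planted reads."""
    _, truth = dataset
    profiles = {p.family: p for p in pipeline_results["profiles"]}
    for planted in truth.planted_mirnas:
        if not planted.conserved:
            continue
        prof = profiles[planted.family]
        for lib, n in truth.planted_counts[planted.name].items():
            assert prof.counts.get(lib, 0) >= n


def test_sharing_percentages():
    sets = {"A": {"a", "b", "c"}, "B": {"c", "d"}}
    ea, eb, sh = unique_mirna_sharing(sets, ("A", "B"))
    assert (ea, eb, sh) == (50.0, 25.0, 25.0)
    assert ea + eb + sh == pytest.approx(100.0)


def test_sharing_identical_sets():
    sets = {"A": {"x", "y"}, "B": {"x", "y"}}
    assert unique_mirna_sharing(sets, ("A", "B"))[2] == 100.0


def test_sharing_disjoint_sets():
    sets = {"A": {"x"}, "B": {"y"}}
    assert unique_mirna_sharing(sets, ("A", "B"))[2] == 0.0


def test_sharing_empty_union_signaled():
    sets = {"A": set(), "B": set()}
    with pytest.raises(ValueError):
        unique_mirna_sharing(sets, ("A", "B"))


def test_sharing_missing_library():
    with pytest.raises(ConfigurationError):
        unique_mirna_sharing({"A": {"x"}}, ("A", "B"))
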