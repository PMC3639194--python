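import hashlib
import json
from collections import Counter
from pathlib import Path

import numpy as np
import pytest

from anther_smallrna.errors import ConfigurationError
from anther_smallrna.novel_mirna import evaluate_hairpin
from anther_smallrna.preprocess import length_histogram
from anther_smallrna.synthetic_data import (
    SimulationConfig,
    dinucleotide_shuffle,
    generate_dataset,
    plant_hairpin,
)

TINY = dict(
    library_depth=4000,
    n_planted_mirnas=4,
    n_conserved=2,
    n_transcripts=10,
    degradome_depth=2000,
)


def _hash_tree(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def test_same_seed_byte_identical(tmp_path):
    cfg = SimulationConfig(seed=21, **TINY)
    generate_dataset(cfg, tmp_path / "a")
    generate_dataset(cfg, tmp_path / "b")
    assert _hash_tree(tmp_path / "a") == _hash_tree(tmp_path / "b")


def test_different_seed_differs(tmp_path):
    generate_dataset(SimulationConfig(seed=1, **TINY), tmp_path / "a")
    generate_dataset(SimulationConfig(seed=2, **TINY), tmp_path / "b")
    assert _hash_tree(tmp_path / "a") != _hash_tree(tmp_path / "b")


def test_invalid_length_dist_rejected():
    cfg = SimulationConfig(length_dist={20: 0.5, 24: 0.4})
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_invalid_fold_change_rejected():
    cfg = SimulationConfig(de_spec=[("x", "Mar-F-1", "Mar-S-1", -2.0)])
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_duplicate_library_ids_rejected():
    cfg = SimulationConfig()
    cfg.libraries = cfg.libraries + [cfg.libraries[0]]
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_modal_length_is_24(pipeline_results):
    hist = length_histogram(pipeline_results["tag_table"])
    assert max(hist, key=hist.get) == 24


def test_planted_count_conservation(dataset, pipeline_results):
    """Pooled tag count of each planted mature equals its simulated reads."""
    _, truth = dataset
    table = pipeline_results["tag_table"]
    for planted in truth.planted_mirnas:
        expected = truth.planted_counts[planted.name]
        got = table.counts(planted.mature)
        for lib, n in expected.items():
            assert got.get(lib, 0) == n


def test_structural_fraction_within_3sd(dataset, pipeline_results, sim_config):
    summary = pipeline_results["summary"]
    depth = sim_config.library_depth
    p = sim_config.structural_fraction
    sd = (p * (1 - p) / depth) ** 0.5
    for lib in summary.columns:
        measured = (
            summary.loc[["rRNA", "tRNA", "snRNA", "snoRNA"], lib].sum()
            / summary.loc["Total reads", lib]
        )
        assert abs(measured - p) <= 3 * sd + 1e-9


def test_degradome_peak_at_planted_site(dataset):
    """5'-end histogram has its unique maximum at each planted position."""
    paths, truth = dataset
    from anther_smallrna.io import read_fasta

    transcripts = dict(read_fasta(paths["transcripts"]))
    reads = [seq for _, seq in read_fasta(paths["degradome"])]
    by_target = {t.transcript: t for t in truth.planted_targets}
    hist: dict[str, Counter] = {tid: Counter() for tid in by_target}
    for read in reads:
        for tid, target in by_target.items():
            pos = transcripts[tid].find(read)
            while pos >= 0:
                hist[tid][pos + 1] += 1
                pos = transcripts[tid].find(read, pos + 1)
    for tid, target in by_target.items():
        counts = hist[tid]
        top, top_n = counts.most_common(1)[0]
        assert top == target.cleavage_position
        others = [n for p, n in counts.items() if p != top]
        assert not others or top_n > max(others)


def test_planted_mature_is_substring_of_precursor(dataset):
    _, truth = dataset
    for planted in truth.planted_mirnas:
        assert 18 <= len(planted.mature) <= 26
        assert planted.mature in planted.precursor


def test_cleavage_positions_inside_transcripts(dataset):
    paths, truth = dataset
    from anther_smallrna.io import read_fasta

    transcripts = dict(read_fasta(paths["transcripts"]))
    for target in truth.planted_targets:
        assert 1 <= target.cleavage_position <= len(transcripts[target.transcript])


def test_ground_truth_manifest_json(tmp_path):
    cfg = SimulationConfig(seed=4, **TINY)
    paths, truth = generate_dataset(cfg, tmp_path)
    payload = json.loads(paths["ground_truth"].read_text())
    assert len(payload["planted_mirnas"]) == cfg.n_planted_mirnas
    assert len(payload["planted_targets"]) == cfg.n_planted_mirnas


# ---------------------------------------------------------------------------
# hairpin planting


def test_plant_hairpin_5p_contains_mature_verbatim():
    mature = "ACGGTTAGCCATGCATGACGA"
    hp = plant_hairpin(mature, "5p", seed=0)
    assert hp.precursor.startswith(mature)
    assert hp.mature_start == 1


def test_plant_hairpin_roundtrip_accepted():
    mature = "TTGGCACGCATCGATCGGTAC"
    for arm in ("5p", "3p"):
        hp = plant_hairpin(mature, arm, seed=7)
        cand = evaluate_hairpin(hp.precursor, hp.mature_start - 1, len(mature))
        assert cand.accepted
        assert cand.energy <= -18.0


def test_plant_hairpin_17nt_error():
    with pytest.raises(ValueError):
        plant_hairpin("ACGTACGTACGTACGTA", "5p", seed=0)


def test_plant_hairpin_bad_arm():
    with pytest.raises(ValueError):
        plant_hairpin("ACGTACGTACGTACGTACGTA", "stem", seed=0)


def test_dinucleotide_shuffle_preserves_counts():
    rng = np.random.default_rng(0)
    seq = "ACGTACGTTTGCAGCATGCTGATCGTACCGGTTAAGCTATGCA"
    for _ in range(5):
        shuffled = dinucleotide_shuffle(seq, rng)
        assert len(shuffled) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]
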