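"""Synthetic dataset generator with planted ground truth.

Generates every input the pipeline consumes -- transcripts, structural
ncRNA references, a mature-miRNA reference, six small-RNA FASTQ libraries,
and a degradome FASTA -- together with a manifest of what was planted:
miRNA hairpin precursors embedded in transcripts, cleavage targets whose
degradome signal piles up exactly at the nucleotide paired to miRNA
position 10, and between-library fold changes.  Everything is driven by a
single seed; the same configuration always produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .io import write_fasta, write_fastq
from .novel_mirna import HairpinCriteria, evaluate_hairpin
from .preprocess import Library, default_libraries
from .seqs import normalize, revcomp, to_rna

_BASES = np.array(list("ACGT"))

#: tag-length probabilities with the mode at 24 nt, echoing the pooled
#: library size distribution (21-24 nt dominant, 24 nt most abundant)
DEFAULT_LENGTH_DIST: dict[int, float] = {
    18: 0.02, 19: 0.03, 20: 0.05, 21: 0.12, 22: 0.08, 23: 0.10,
    24: 0.35, 25: 0.08, 26: 0.05, 27: 0.04, 28: 0.03, 29: 0.02, 30: 0.03,
}

_STRUCTURAL_SPLIT = {"rRNA": 0.62, "tRNA": 0.25, "snRNA": 0.07, "snoRNA": 0.06}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_transcripts: int = 60
    transcript_len_range: tuple[int, int] = (400, 700)
    n_planted_mirnas: int = 10
    n_conserved: int = 5
    libraries: list[Library] = field(default_factory=default_libraries)
    library_depth: int = 50_000
    length_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    structural_fraction: float = 0.04
    mirna_fraction: float = 0.10
    de_spec: list[tuple[str, str, str, float]] = field(default_factory=list)
    degradome_depth: int = 20_000
    degradome_signal_fraction: float = 0.25
    #: relative per-position rate of uniform background degradome 5' ends
    background_noise: float = 1.0
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    mature_len_choices: tuple[int, ...] = (20, 21, 22)
    degradome_len_choices: tuple[int, ...] = (20, 21)
    background_pool_size: int | None = None

    def validate(self) -> None:
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-6:
            raise ConfigurationError("length_dist probabilities must sum to 1")
        if any(not 18 <= k <= 30 for k in self.length_dist):
            raise ConfigurationError("length_dist keys must lie in 18..30")
        for spec in self.de_spec:
            if len(spec) != 4 or spec[3] <= 0:
                raise ConfigurationError(f"invalid de_spec entry {spec!r}")
        ids = [l.id for l in self.libraries]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("library ids must be distinct")
        if not 0 <= self.structural_fraction + self.mirna_fraction < 1:
            raise ConfigurationError("structural + miRNA fractions must be < 1")
        if self.n_conserved > self.n_planted_mirnas:
            raise ConfigurationError("n_conserved cannot exceed n_planted_mirnas")
        if self.n_transcripts < 2 * self.n_planted_mirnas:
            raise ConfigurationError("need at least 2 transcripts per planted miRNA")
        if not 0 <= self.degradome_signal_fraction <= 1:
            raise ConfigurationError("degradome_signal_fraction must be in [0, 1]")

    @property
    def pool_size(self) -> int:
        return self.background_pool_size or max(1000, self.library_depth // 5)


@dataclass
class PlantedMirna:
    name: str
    mature: str  # DNA, internal representation
    precursor: str
    arm: str
    transcript: str
    precursor_start: int  # 1-based on transcript
    precursor_end: int
    mature_start: int  # 1-based on transcript
    conserved: bool
    family: str | None


@dataclass
class PlantedTarget:
    mirna: str
    transcript: str
    site_start: int  # 1-based start of the complementary site
    site_end: int
    cleavage_position: int  # target nucleotide paired to miRNA position 10


@dataclass
class GroundTruth:
    planted_mirnas: list[PlantedMirna] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_de: list[tuple[str, str, str, float]] = field(default_factory=list)
    #: simulated read counts: miRNA name -> library id -> count
    planted_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_mirnas": [asdict(m) for m in self.planted_mirnas],
            "planted_targets": [asdict(t) for t in self.planted_targets],
            "planted_de": [list(d) for d in self.planted_de],
            "planted_counts": self.planted_counts,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class PlantedHairpin:
    precursor: str
    mature_start: int  # 1-based within the precursor
    mature_end: int
    arm: str


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (random Eulerian walk)."""
    seq = normalize(sequence)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for succ in edges.values():
        rng.shuffle(succ)
    # Hierholzer from the original start vertex
    stack, trail = [seq[0]], []
    while stack:
        v = stack[-1]
        if edges.get(v):
            stack.append(edges[v].pop())
        else:
            trail.append(stack.pop())
    return "".join(reversed(trail))


def plant_hairpin(mature: str, arm: str, seed: int) -> PlantedHairpin:
    """Build a precursor that folds into an accepted hairpin for ``mature``.

    The mature occupies the requested arm verbatim; the other arm carries a
    reverse complement of the mature minus its 2-nt 3' Dicer overhang, with
    a terminal loop in between.  Construction is retried with fresh random
    loop/overhang sequences until the default acceptance criteria pass.
    """
    mat = normalize(mature)
    if not 18 <= len(mat) <= 26:
        raise ValueError(f"mature length must be 18-26 nt (got {len(mat)})")
    if arm not in ("5p", "3p"):
        raise ValueError(f"arm must be '5p' or '3p' (got {arm!r})")
    rng = np.random.default_rng(seed)
    star = revcomp(mat[: len(mat) - 2])
    for _ in range(40):
        loop = "".join(rng.choice(_BASES, 8))
        overhang = "".join(rng.choice(_BASES, 2))
        if arm == "5p":
            precursor = mat + loop + star + overhang
            mature_start = 1
        else:
            precursor = star + overhang + loop + mat
            mature_start = len(star) + 2 + len(loop) + 1
        cand = evaluate_hairpin(precursor, mature_start - 1, len(mat), HairpinCriteria())
        if cand.accepted and cand.arm == arm:
            return PlantedHairpin(precursor, mature_start, mature_start + len(mat) - 1, arm)
    raise RuntimeError("could not construct an acceptable hairpin")  # pragma: no cover


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _clean_tag(rng: np.random.Generator, n: int, forbidden: str) -> str:
    """Random tag free of the adapter probe, poly-A runs and duplicates."""
    for _ in range(100):
        s = _random_seq(rng, n)
        if forbidden in s:
            continue
        if s.count("A") >= 0.8 * n:
            continue
        return s
    raise RuntimeError("tag sampling failed")  # pragma: no cover


def generate_dataset(config: SimulationConfig, outdir) -> tuple[dict, GroundTruth]:
    """Write the full synthetic input set under ``outdir``.

    Returns ``(paths, ground_truth)``; ``paths`` maps logical names to the
    files written.  Same config (including seed) -> byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    adapter3 = normalize(config.adapter3)
    probe = adapter3[:8]
    truth = GroundTruth(planted_de=list(config.de_spec))

    lo, hi = config.transcript_len_range
    t_ids = [f"TC{i + 1:05d}" for i in range(config.n_transcripts)]
    transcripts = {tid: _random_seq(rng, int(rng.integers(lo, hi + 1))) for tid in t_ids}

    # --- planted miRNAs: hairpin precursors embedded in host transcripts
    matures: list[str] = []
    for i in range(config.n_planted_mirnas):
        conserved = i < config.n_conserved
        name = f"ghr-miR9{i + 1:02d}" if conserved else f"can-m{i + 1:03d}"
        length = int(rng.choice(config.mature_len_choices))
        while True:
            mat = _clean_tag(rng, length, probe)
            if mat not in matures:
                break
        matures.append(mat)
        arm = "5p" if i % 2 == 0 else "3p"
        hp = plant_hairpin(mat, arm, seed=int(rng.integers(2**31)))
        tid = t_ids[i]
        tseq = transcripts[tid]
        pos = int(rng.integers(30, len(tseq) - len(hp.precursor) - 30))
        transcripts[tid] = tseq[:pos] + hp.precursor + tseq[pos + len(hp.precursor):]
        truth.planted_mirnas.append(
            PlantedMirna(
                name=name,
                mature=mat,
                precursor=hp.precursor,
                arm=arm,
                transcript=tid,
                precursor_start=pos + 1,
                precursor_end=pos + len(hp.precursor),
                mature_start=pos + hp.mature_start,
                conserved=conserved,
                family=f"miR9{i + 1:02d}" if conserved else None,
            )
        )

    # --- planted cleavage targets: perfect complement embedded elsewhere;
    # the cleavage position is the target base paired to miRNA position 10
    for i, planted in enumerate(truth.planted_mirnas):
        tid = t_ids[config.n_planted_mirnas + i]
        tseq = transcripts[tid]
        site = revcomp(planted.mature)
        L = len(site)
        pos = int(rng.integers(30, len(tseq) - L - 40))
        transcripts[tid] = tseq[:pos] + site + tseq[pos + L:]
        site_start = pos + 1
        truth.planted_targets.append(
            PlantedTarget(
                mirna=planted.name,
                transcript=tid,
                site_start=site_start,
                site_end=site_start + L - 1,
                cleavage_position=site_start + L - 10,
            )
        )

    paths: dict = {}
    paths["transcripts"] = outdir / "transcripts.fasta"
    write_fasta(paths["transcripts"], [(tid, transcripts[tid]) for tid in t_ids])

    # --- structural ncRNA references
    ncrna_refs: dict[str, list[tuple[str, str]]] = {}
    ref_lens = {"rRNA": 1200, "tRNA": 90, "snRNA": 180, "snoRNA": 140}
    paths["ncrna"] = {}
    for cls, ref_len in ref_lens.items():
        refs = []
        for j in range(3):
            while True:
                seq = _random_seq(rng, ref_len)
                if probe not in seq:
                    break
            refs.append((f"{cls}_{j + 1}", seq))
        ncrna_refs[cls] = refs
        paths["ncrna"][cls] = outdir / f"ncrna_{cls}.fasta"
        write_fasta(paths["ncrna"][cls], refs)

    # --- mature/precursor reference for the conserved subset (miRBase style)
    ref_records = []
    for planted in truth.planted_mirnas:
        if planted.conserved:
            ref_records.append((planted.name, to_rna(planted.mature)))
            ref_records.append((planted.name.replace("miR", "MIR"), to_rna(planted.precursor)))
    paths["mature_ref"] = outdir / "mirna_reference.fasta"
    write_fasta(paths["mature_ref"], ref_records)

    # --- per-library small RNA reads
    names = [m.name for m in truth.planted_mirnas]
    base_w = 10 ** rng.uniform(0, 2, config.n_planted_mirnas)
    lib_weights = {lib.id: base_w.copy() for lib in config.libraries}
    for name, lib_a, lib_b, fold in config.de_spec:
        if name not in names:
            raise ConfigurationError(f"de_spec references unknown miRNA {name!r}")
        for lib in (lib_a, lib_b):
            if lib not in lib_weights:
                raise ConfigurationError(f"de_spec references unknown library {lib!r}")
        lib_weights[lib_b][names.index(name)] *= fold

    pool = _background_pool(rng, config, probe, set(matures))
    pool_base_w = rng.lognormal(0.0, 1.0, len(pool))
    lengths = np.array(sorted(config.length_dist))
    length_p = np.array([config.length_dist[k] for k in lengths])
    length_p = length_p / length_p.sum()

    truth.planted_counts = {name: {} for name in names}
    paths["libraries"] = {}
    composition: dict[str, dict[str, int]] = {}
    sf, mf = config.structural_fraction, config.mirna_fraction
    for lib in config.libraries:
        n_str, n_mir, n_bg = rng.multinomial(config.library_depth, [sf, mf, 1 - sf - mf])
        reads: list[str] = []
        # planted miRNA reads (exact mature tags)
        w = lib_weights[lib.id]
        mir_counts = rng.multinomial(n_mir, w / w.sum())
        for name, mat, cnt in zip(names, matures, mir_counts):
            truth.planted_counts[name][lib.id] = int(cnt)
            reads.extend([mat] * int(cnt))
        # structural reads: substrings of the ncRNA references
        cls_names = list(_STRUCTURAL_SPLIT)
        cls_counts = rng.multinomial(n_str, list(_STRUCTURAL_SPLIT.values()))
        for cls, cnt in zip(cls_names, cls_counts):
            refs = ncrna_refs[cls]
            for _ in range(int(cnt)):
                for _try in range(10):
                    _, ref_seq = refs[int(rng.integers(len(refs)))]
                    k = int(rng.choice(lengths, p=length_p))
                    start = int(rng.integers(0, len(ref_seq) - k + 1))
                    sub = ref_seq[start : start + k]
                    if probe not in sub and sub.count("A") < 0.8 * k:
                        break
                reads.append(sub)
        # background tags from the shared pool, library-specific weights
        jitter = rng.lognormal(0.0, 0.5, len(pool))
        pw = pool_base_w * jitter
        bg_counts = rng.multinomial(n_bg, pw / pw.sum())
        idx = np.repeat(np.arange(len(pool)), bg_counts)
        reads.extend(pool[i] for i in idx)

        order = rng.permutation(len(reads))
        path = outdir / f"{lib.id}.fastq"
        write_fastq(
            path,
            ((f"{lib.id}_r{k + 1:07d}", reads[i] + adapter3) for k, i in enumerate(order)),
        )
        paths["libraries"][lib.id] = path
        composition[lib.id] = {"structural": int(n_str), "mirna": int(n_mir), "background": int(n_bg)}

    # --- degradome reads: signal piled at the planted cleavage positions,
    # uniform background 5' ends elsewhere
    deg_reads: list[str] = []
    n_signal = int(round(config.degradome_depth * config.degradome_signal_fraction))
    if truth.planted_targets and n_signal:
        per_target = rng.multinomial(n_signal, [1 / len(truth.planted_targets)] * len(truth.planted_targets))
        for target, cnt in zip(truth.planted_targets, per_target):
            tseq = transcripts[target.transcript]
            for _ in range(int(cnt)):
                k = int(rng.choice(config.degradome_len_choices))
                deg_reads.append(tseq[target.cleavage_position - 1 : target.cleavage_position - 1 + k])
    n_bg_deg = config.degradome_depth - n_signal
    for _ in range(n_bg_deg):
        tid = t_ids[int(rng.integers(len(t_ids)))]
        tseq = transcripts[tid]
        k = int(rng.choice(config.degradome_len_choices))
        start = int(rng.integers(0, len(tseq) - k + 1))
        deg_reads.append(tseq[start : start + k])
    order = rng.permutation(len(deg_reads))
    paths["degradome"] = outdir / "degradome.fasta"
    write_fasta(paths["degradome"], ((f"d{k + 1:07d}", deg_reads[i]) for k, i in enumerate(order)))

    # --- ground truth manifest (JSON + targets TSV)
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(truth.to_json() + "\n")
    paths["ground_truth_targets"] = outdir / "ground_truth_targets.tsv"
    with open(paths["ground_truth_targets"], "w") as fh:
        fh.write("mirna\ttranscript\tsite_start\tsite_end\tcleavage_position\n")
        for t in truth.planted_targets:
            fh.write(f"{t.mirna}\t{t.transcript}\t{t.site_start}\t{t.site_end}\t{t.cleavage_position}\n")
    paths["composition"] = outdir / "composition.json"
    paths["composition"].write_text(json.dumps(composition, indent=2, sort_keys=True) + "\n")
    return paths, truth


def _background_pool(
    rng: np.random.Generator, config: SimulationConfig, probe: str, matures: set[str]
) -> list[str]:
    lengths = np.array(sorted(config.length_dist))
    length_p = np.array([config.length_dist[k] for k in lengths], dtype=float)
    length_p /= length_p.sum()
    pool: list[str] = []
    seen: set[str] = set(matures)
    while len(pool) < config.pool_size:
        k = int(rng.choice(lengths, p=length_p))
        s = _random_seq(rng, k)
        if probe in s or s.count("A") >= 0.8 * k or s in seen:
            continue
        seen.add(s)
        pool.append(s)
    return pool
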