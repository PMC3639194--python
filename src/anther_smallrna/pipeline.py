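"""End-to-end orchestration: run every stage from a single configuration.

Stage order follows the analysis workflow: cleanup -> annotation ->
conserved families -> novel miRNAs -> differential expression ->
degradome.  Every parameter (including all defaults) is stamped into the
run manifest so that choices are always visible, and a fixed seed makes
the whole report bundle byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .annotate import classify_structural, format_summary, summary_counts
from .conserved_profile import (
    assign_families,
    family_abundance,
    family_frame,
    load_mirbase_fasta,
    unique_mirna_sharing,
)
from .degradome import (
    build_kmer_index,
    call_cleavage,
    calls_frame,
    find_candidate_sites,
    map_degradome,
    normalize_signatures,
    tplot_table,
)
from .diff_expr import call_differential, results_frame
from .errors import ConfigurationError
from .io import read_fasta, read_fastq
from .novel_mirna import HairpinCriteria, find_hairpins
from .preprocess import clean_reads, filter_and_collapse, length_histogram
from .seqs import to_rna
from .synthetic_data import SimulationConfig, generate_dataset

STAGE_ORDER = ("simulate", "preprocess", "annotate", "conserved", "novel", "de", "degradome")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    outdir: Path
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    # preprocess
    adapter3: str | None = None  # defaults to the simulation adapter
    adapter5: str | None = None
    min_len: int = 18
    max_len: int = 30
    # conserved
    max_mismatch: int = 2
    plant_reference: Path | None = None  # optional tier-2 FASTA
    # novel
    novel_min_reads: int = 4
    hairpin_criteria: HairpinCriteria = field(default_factory=HairpinCriteria)
    window_up: int = 20
    window_down: int = 220
    # differential expression
    alpha: float = 0.01
    min_abs_log2fc: float = 1.0
    # degradome
    max_duplex_score: float = 4.0
    degradome_read_lengths: tuple[int, ...] = (20, 21)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        stages = {s: True for s in STAGE_ORDER}
        stages.update(raw.pop("stages", {}))
        crit = HairpinCriteria(**raw.pop("hairpin_criteria", {}))
        if "outdir" not in raw:
            raise ConfigurationError("pipeline config requires 'outdir'")
        raw["outdir"] = Path(raw["outdir"])
        if "degradome_read_lengths" in raw:
            raw["degradome_read_lengths"] = tuple(raw["degradome_read_lengths"])
        return cls(simulation=sim, stages=stages, hairpin_criteria=crit, **raw)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage context is the point
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return run

    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order.

    Returns a results dictionary holding the in-memory objects and the
    paths of every report file written under ``outdir/report``.
    """
    outdir = Path(config.outdir)
    report_dir = outdir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {"report_dir": report_dir, "report_files": {}}
    parameters = _jsonable(config)
    parameters.pop("outdir", None)  # keep the manifest location-independent
    manifest: dict[str, Any] = {
        "version": __version__,
        "parameters": parameters,
        "stages": {},
    }

    paths, truth = _stage("simulate")(generate_dataset)(config.simulation, outdir / "data")
    results["input_paths"] = paths
    results["ground_truth"] = truth
    manifest["stages"]["simulate"] = {
        "enabled": bool(config.stages.get("simulate", True)),
        "n_transcripts": config.simulation.n_transcripts,
        "n_planted_mirnas": config.simulation.n_planted_mirnas,
    }

    # ---- preprocess ------------------------------------------------------
    adapter3 = config.adapter3 or config.simulation.adapter3
    lib_meta = config.simulation.libraries

    @_stage("preprocess")
    def _preprocess():
        reads_by_lib = {
            lib.id: clean_reads(
                (seq for _, seq in read_fastq(paths["libraries"][lib.id])),
                adapter3,
                config.adapter5,
            )
            for lib in lib_meta
        }
        return filter_and_collapse(
            reads_by_lib, min_len=config.min_len, max_len=config.max_len, library_meta=lib_meta
        )

    table, libraries = _preprocess()
    results["tag_table"], results["libraries"] = table, libraries
    table.write_tsv(outdir / "tags.tsv")
    manifest["stages"]["preprocess"] = {
        "unique_tags": len(table),
        "total_reads": {l.id: l.total_reads for l in libraries},
    }

    hist_path = report_dir / "length_distribution.tsv"
    _write_length_table(hist_path, table, libraries)
    results["report_files"]["length_distribution"] = hist_path

    # ---- structural annotation ------------------------------------------
    @_stage("annotate")
    def _annotate():
        refs = {cls: read_fasta(p) for cls, p in paths["ncrna"].items()}
        return classify_structural(table, refs)

    records = _annotate()
    results["annotations"] = records
    summary = summary_counts(records, table, libraries)
    fmt = format_summary(summary)
    summary_path = report_dir / "structural_summary.tsv"
    fmt.to_csv(summary_path, sep="\t")
    results["summary"] = summary
    results["report_files"]["structural_summary"] = summary_path
    manifest["stages"]["annotate"] = {
        "structural_reads": {
            lib.id: int(summary.loc[list(paths["ncrna"]), lib.id].sum()) for lib in libraries
        }
    }

    # ---- conserved families ---------------------------------------------
    @_stage("conserved")
    def _conserved():
        species_refs = load_mirbase_fasta(paths["mature_ref"])
        plant_refs = (
            load_mirbase_fasta(config.plant_reference) if config.plant_reference else []
        )
        candidates = [
            s for s in table.sequences() if records[s].category == "unannotated"
        ]
        assignments = assign_families(
            candidates, species_refs, plant_refs, max_mismatch=config.max_mismatch
        )
        return assignments, family_abundance(assignments, table, libraries)

    assignments, profiles = _conserved()
    results["assignments"], results["profiles"] = assignments, profiles
    fam_path = report_dir / "family_abundance.tsv"
    family_frame(profiles, libraries).to_csv(fam_path, sep="\t", index=False)
    results["report_files"]["family_abundance"] = fam_path
    manifest["stages"]["conserved"] = {
        "families": len(profiles),
        "assigned_tags": len(assignments),
    }

    # ---- novel miRNAs ----------------------------------------------------
    transcripts = dict(read_fasta(paths["transcripts"]))

    @_stage("novel")
    def _novel():
        accepted = {}
        for tag in table:
            seq = tag.sequence
            if records[seq].category != "unannotated" or seq in assignments:
                continue
            if tag.total() < config.novel_min_reads:
                continue
            cand = find_hairpins(
                seq,
                transcripts,
                config.hairpin_criteria,
                up=config.window_up,
                down=config.window_down,
            )
            if cand is not None and cand.accepted:
                accepted[seq] = cand
        return accepted

    novel = _novel() if config.stages.get("novel", True) else {}
    results["novel"] = novel
    if config.stages.get("novel", True):
        novel_path = report_dir / "novel_candidates.tsv"
        with open(novel_path, "w") as fh:
            fh.write("sequence\ttranscript\tcount\tarm\tenergy\tmature_start\n")
            for seq in sorted(novel):
                c = novel[seq]
                total = sum(table.counts(seq).values())
                fh.write(
                    f"{to_rna(seq)}\t{c.transcript}\t{total}\t{c.arm}\t{c.energy:.2f}\t{c.mature_start}\n"
                )
        with open(outdir / "novel_precursors.fasta", "w") as fa, open(
            outdir / "novel_structures.txt", "w"
        ) as db:
            for i, seq in enumerate(sorted(novel), start=1):
                c = novel[seq]
                fa.write(f">novel_{i:04d} {c.transcript}\n{c.precursor}\n")
                db.write(f">novel_{i:04d}\n{c.precursor}\n{c.structure} ({c.energy:.2f})\n")
        results["report_files"]["novel_candidates"] = novel_path
    manifest["stages"]["novel"] = {"accepted": len(novel)}

    # ---- unique-miRNA sharing (conserved + novel presence per library) ---
    mirna_sets = {
        l.id: {
            s
            for s in set(assignments) | set(novel)
            if table.counts(s).get(l.id, 0) >= 1
        }
        for l in libraries
    }
    pairs = _genotype_pairs(libraries)
    share_path = report_dir / "unique_mirna_sharing.tsv"
    with open(share_path, "w") as fh:
        fh.write("library_a\tlibrary_b\texclusive_a_pct\texclusive_b_pct\tshared_pct\n")
        for a, b in pairs:
            try:
                ea, eb, sh = unique_mirna_sharing(mirna_sets, (a, b))
            except ValueError:
                ea = eb = sh = float("nan")
            fh.write(f"{a}\t{b}\t{ea:.2f}\t{eb:.2f}\t{sh:.2f}\n")
    results["mirna_sets"] = mirna_sets
    results["report_files"]["unique_mirna_sharing"] = share_path

    # ---- differential expression (family level, per stage pair) ----------
    de_results = {}
    if config.stages.get("de", True):

        @_stage("de")
        def _de():
            out = {}
            totals = {l.id: l.total_reads for l in libraries}
            for a, b in pairs:
                counts = {
                    p.family: (p.counts.get(a, 0), p.counts.get(b, 0)) for p in profiles
                }
                out[(a, b)] = call_differential(
                    counts,
                    (a, b),
                    totals=(totals[a], totals[b]),
                    alpha=config.alpha,
                    min_abs_log2fc=config.min_abs_log2fc,
                )
            return out

        de_results = _de()
        for (a, b), res in de_results.items():
            p = report_dir / f"de_{a}_vs_{b}.tsv"
            results_frame(res).to_csv(p, sep="\t", index=False)
            results["report_files"][f"de_{a}_vs_{b}"] = p
    results["de"] = de_results
    manifest["stages"]["de"] = {
        "pairs": [list(p) for p in pairs],
        "significant": {f"{a}_vs_{b}": sum(r.significant for r in res) for (a, b), res in de_results.items()},
    }

    # ---- degradome -------------------------------------------------------
    calls = []
    if config.stages.get("degradome", True):

        @_stage("degradome")
        def _degradome():
            reads = [seq for _, seq in read_fasta(paths["degradome"])]
            lengths = config.degradome_read_lengths
            index = build_kmer_index(transcripts, lengths)
            sized = [r for r in reads if len(r) in lengths]
            mapped = sum(1 for r in sized if r in index)
            ncrna_haystack = "|".join(
                seq for p in paths["ncrna"].values() for _, seq in read_fasta(p)
            )
            structural = sum(1 for r in sized if r in index and r in ncrna_haystack)
            signatures = map_degradome(sized, transcripts, lengths, index=index)
            normalize_signatures(signatures, mapped, structural)
            mirnas = {m.name: m.mature for m in results["ground_truth"].planted_mirnas if m.conserved}
            mirnas.update({f"novel:{to_rna(s)}": s for s in novel})
            sites = []
            for name in sorted(mirnas):
                for aln in find_candidate_sites(mirnas[name], transcripts, config.max_duplex_score):
                    aln.mirna = name  # label sites with the miRNA id
                    sites.append(aln)
            return call_cleavage(sites, signatures), signatures

        calls, signatures = _degradome()
        results["signatures"] = signatures
        calls_path = report_dir / "degradome_calls.tsv"
        calls_frame(calls).to_csv(calls_path, sep="\t", index=False)
        results["report_files"]["degradome_calls"] = calls_path
        tplot_dir = report_dir / "tplots"
        tplot_dir.mkdir(exist_ok=True)
        for tid in sorted({c.transcript for c in calls}):
            tplot_table(tid, signatures, calls).to_csv(tplot_dir / f"{tid}.tsv", sep="\t", index=False)
        results["tplot_dir"] = tplot_dir
    results["calls"] = calls
    manifest["stages"]["degradome"] = {
        "enabled": bool(config.stages.get("degradome", True)),
        "calls": len(calls),
    }

    manifest_path = report_dir / "manifest.json"
    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")
    results["report_files"]["manifest"] = manifest_path
    results["manifest"] = manifest
    return results


def _genotype_pairs(libraries) -> list[tuple[str, str]]:
    """Pair libraries of the same stage across the two genotypes."""
    by_stage: dict[str, dict[str, str]] = {}
    for lib in libraries:
        by_stage.setdefault(lib.stage, {})[lib.genotype] = lib.id
    pairs = []
    for stage in ("meiosis", "tetrad", "uninucleate"):
        d = by_stage.get(stage, {})
        if "WT" in d and "GMS" in d:
            pairs.append((d["WT"], d["GMS"]))
    return pairs


def _write_length_table(path, table, libraries) -> None:
    hist_all = length_histogram(table)
    per_geno = {}
    for geno in ("WT", "GMS"):
        libs = [l.id for l in libraries if l.genotype == geno]
        per_geno[geno] = length_histogram(table, libs) if libs else {}
    with open(path, "w") as fh:
        fh.write("length\tWT\tGMS\ttotal\n")
        for length in sorted(hist_all):
            fh.write(
                f"{length}\t{per_geno['WT'].get(length, 0)}\t{per_geno['GMS'].get(length, 0)}\t{hist_all[length]}\n"
            )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item") and callable(obj.item):  # numpy scalars
        return obj.item()
    return obj
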