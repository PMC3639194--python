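# anther-smallrna

Comparative small-RNA analysis toolkit for paired anther sequencing
libraries (two genotypes x three developmental stages), covering:

- **preprocess** — adapter trimming, read cleanup, the 18–30 nt length
  window, and collapsing to unique tags with per-library counts.
- **annotate** — exact-match partitioning of tags into structural ncRNA
  classes (rRNA / tRNA / snRNA / snoRNA) with a per-library summary table.
- **conserved_profile** — two-tier (species, then all-plant) miRNA family
  assignment, family abundance profiles, and pairwise unique-miRNA sharing.
- **novel_mirna** — transcript mapping, precursor window extraction, a
  built-in base-pair-maximization folding backend (pluggable), and
  hairpin/duplex/energy acceptance criteria; plus a loader for the shipped
  novel-miRNA table (`src/anther_smallrna/fixtures/table2_novel_mirnas.tsv`).
- **diff_expr** — per-feature chi-square tests on 2x2 count tables with a
  Fisher fallback, CPM/log2 fold changes and Benjamini–Hochberg control.
- **degradome** — miRNA:target duplex scoring (mismatch 1, G:U 0.5, gap 1,
  doubled at positions 2–13; score ≤ 4), exhaustive candidate-site
  scanning, degradome signature mapping, TP10M normalization, cleavage
  calls at the site paired to miRNA position 10/11, peak categories 0–4,
  and t-plot tables.
- **synthetic_data** — a seeded generator that writes every input the
  pipeline consumes with planted ground truth (hairpins embedded in
  transcripts, cleavage targets, between-library fold changes).
- **pipeline / cli** — one-command orchestration producing the report
  bundle (summary, length, sharing, family, DE, degradome tables plus a
  run manifest); byte-identical reruns under a fixed seed.

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the acceptance suite (fixture round-trip,
oracle equivalence of the degradome scanner, duplex/TP10M/chi-square spot
checks, synthetic end-to-end recovery, conservation invariants).

## CLI

```sh
anther-smallrna simulate --out data/ --seed 1 --depth 50000
anther-smallrna preprocess data/*.fastq --adapter3 TGGAATTCTCGGGTGCCAAGG --out tags.tsv
anther-smallrna conserved --tags tags.tsv --species-ref data/mirna_reference.fasta --out families.tsv
anther-smallrna novel --tags tags.tsv --transcripts data/transcripts.fasta --out novel.tsv
anther-smallrna de --tags tags.tsv --pair Mar-F-1,Mar-S-1 --out de.tsv
anther-smallrna degradome --reads data/degradome.fasta --transcripts data/transcripts.fasta \
    --mirnas data/mirna_reference.fasta --out calls.tsv
anther-smallrna run --config run.yaml     # full pipeline from YAML
anther-smallrna report                    # summarize the shipped novel-miRNA table
```

A minimal `run.yaml`:

```yaml
outdir: out/
simulation:
  seed: 7
  library_depth: 50000
```

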