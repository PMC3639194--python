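"""Read cleanup, length filtering, and collapsing to unique tags.

The cleanup stage removes adapter sequence and the three read classes that
cannot yield usable inserts (pure adapter, 5' adapter contamination,
poly-A); the collapse stage enforces the 18-30 nt window and aggregates
identical sequences into :class:`SmallRNATag` records with per-library
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .seqs import normalize

MIN_TAG_LEN = 18
MAX_TAG_LEN = 30

GENOTYPES = ("WT", "GMS")
STAGES = ("meiosis", "tetrad", "uninucleate")


@dataclass
class Library:
    """One sequencing library (a genotype x anther-stage combination)."""

    id: str
    genotype: str
    stage: str
    total_reads: int = 0


def default_libraries() -> list[Library]:
    """The six default libraries: Mar-F-* are WT, Mar-S-* the GMS mutant."""
    libs = []
    for geno, code in (("WT", "F"), ("GMS", "S")):
        for i, stage in enumerate(STAGES, start=1):
            libs.append(Library(f"Mar-{code}-{i}", geno, stage))
    return libs


@dataclass
class SmallRNATag:
    """A collapsed unique read sequence with per-library raw counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def total(self) -> int:
        return sum(self.counts.values())


class TagTable:
    """Mapping of unique tag sequence -> per-library counts.

    Insertion order of sequences is preserved; all aggregate operations
    (totals, histograms) are order-invariant.
    """

    def __init__(self, libraries: Sequence[str]):
        self.libraries = list(libraries)
        self._counts: dict[str, dict[str, int]] = {}

    def add(self, sequence: str, library: str, n: int = 1) -> None:
        if library not in self.libraries:
            raise KeyError(f"unknown library {library!r}")
        per_lib = self._counts.setdefault(sequence, {})
        per_lib[library] = per_lib.get(library, 0) + n

    def counts(self, sequence: str) -> dict[str, int]:
        return dict(self._counts.get(sequence, {}))

    def sequences(self) -> list[str]:
        return list(self._counts)

    def total(self, library: str) -> int:
        return sum(c.get(library, 0) for c in self._counts.values())

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._counts

    def __iter__(self) -> Iterator[SmallRNATag]:
        for seq, per_lib in self._counts.items():
            yield SmallRNATag(seq, dict(per_lib))

    def to_frame(self) -> pd.DataFrame:
        """Tag table as a DataFrame: sequence, length, one column per library."""
        rows = [
            [seq, len(seq)] + [per.get(lib, 0) for lib in self.libraries]
            for seq, per in self._counts.items()
        ]
        return pd.DataFrame(rows, columns=["sequence", "length"] + self.libraries)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TagTable":
        libs = [c for c in frame.columns if c not in ("sequence", "length")]
        table = cls(libs)
        seq_col = list(frame.columns).index("sequence")
        lib_cols = [list(frame.columns).index(lib) for lib in libs]
        for row in frame.itertuples(index=False, name=None):
            seq = row[seq_col]
            for lib, col in zip(libs, lib_cols):
                if row[col]:
                    table.add(seq, lib, int(row[col]))
        return table

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TagTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def clean_reads(
    reads: Iterable[str],
    adapter3: str,
    adapter5: str | None = None,
    *,
    min_adapter_match: int = 8,
    polya_fraction: float = 0.8,
    drop_ambiguous: bool = True,
) -> Iterator[str]:
    """Trim the 3' adapter and drop unusable reads.

    The 3' adapter is trimmed at the first exact occurrence of its
    ``min_adapter_match``-nt prefix.  Discarded: reads whose insert is empty
    (pure adapter), reads still containing the 5' adapter, inserts that are
    >= ``polya_fraction`` adenine, and (by default) inserts containing N.
    Reads without any adapter match are passed through untrimmed; overlong
    inserts are left for the length filter.
    """
    adapter3 = normalize(adapter3)
    if len(adapter3) < min_adapter_match:
        raise ConfigurationError(
            f"3' adapter must be at least {min_adapter_match} nt (got {len(adapter3)})"
        )
    probe = adapter3[:min_adapter_match]
    a5 = normalize(adapter5) if adapter5 else None
    for read in reads:
        seq = normalize(read)
        idx = seq.find(probe)
        insert = seq[:idx] if idx >= 0 else seq
        if not insert:
            continue  # no insert tag
        if a5 and a5 in insert:
            continue  # 5' adapter contamination
        if insert.count("A") >= polya_fraction * len(insert):
            continue  # poly-A
        if drop_ambiguous and "N" in insert:
            continue
        yield insert


def filter_and_collapse(
    reads_by_library: Mapping[str, Iterable[str]],
    *,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
    library_meta: Sequence[Library] | None = None,
) -> tuple[TagTable, list[Library]]:
    """Enforce the length window (bounds inclusive) and collapse to tags.

    Returns the tag table and per-library records whose ``total_reads`` is
    the number of retained reads, so that for every library the tag counts
    sum exactly to ``total_reads``.
    """
    lib_ids = list(reads_by_library)
    table = TagTable(lib_ids)
    meta = {l.id: l for l in (library_meta or [])}
    libraries = []
    for lib_id in lib_ids:
        kept = 0
        for seq in reads_by_library[lib_id]:
            if min_len <= len(seq) <= max_len:
                table.add(seq, lib_id)
                kept += 1
        lib = meta.get(lib_id) or _infer_library(lib_id)
        lib.total_reads = kept
        libraries.append(lib)
    return table, libraries


def _infer_library(lib_id: str) -> Library:
    for lib in default_libraries():
        if lib.id == lib_id:
            return lib
    return Library(lib_id, "WT", "meiosis")


def length_histogram(
    table: TagTable,
    libraries: Sequence[str] | None = None,
    *,
    min_len: int = MIN_TAG_LEN,
    max_len: int = MAX_TAG_LEN,
) -> dict[int, int]:
    """Summed read counts per tag length over the selected libraries."""
    libs = list(libraries) if libraries is not None else list(table.libraries)
    hist: dict[int, int] = {}
    for tag in table:
        if not (min_len <= tag.length <= max_len):
            continue
        n = sum(tag.counts.get(lib, 0) for lib in libs)
        if n:
            hist[tag.length] = hist.get(tag.length, 0) + n
    return dict(sorted(hist.items()))
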