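"""Partition tags into structural ncRNA classes vs candidate regulatory RNAs.

A tag is assigned to a structural class iff its sequence (or its reverse
complement) is an exact substring of any reference sequence of that class.
References are supplied per class; no live database queries are made.
Ties across classes are broken by a fixed precedence (rRNA > tRNA > snRNA
> snoRNA by default, the order the classes are conventionally listed in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .preprocess import Library, TagTable
from .seqs import revcomp

STRUCTURAL_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")

#: categories a tag can carry; miRNA_* are assigned by downstream modules
CATEGORIES = STRUCTURAL_CLASSES + ("miRNA_conserved", "miRNA_novel", "unannotated")


@dataclass
class AnnotationRecord:
    sequence: str
    category: str
    evidence: str | None = None


class _ClassIndex:
    """Exact-substring lookup over the references of one class."""

    def __init__(self, refs: Sequence[tuple[str, str]]):
        self._refs = list(refs)
        # concatenated haystack with a separator that never matches a tag
        self._haystack = "|".join(seq for _, seq in self._refs)

    def match(self, tag: str) -> str | None:
        """Return the id of a reference containing ``tag`` or its revcomp."""
        for probe in (tag, revcomp(tag)):
            if probe in self._haystack:
                for ref_id, seq in self._refs:
                    if probe in seq:
                        return ref_id
        return None


def classify_structural(
    table: TagTable,
    refs: Mapping[str, Sequence[tuple[str, str]]],
    precedence: Sequence[str] = STRUCTURAL_CLASSES,
) -> dict[str, AnnotationRecord]:
    """Classify every tag in ``table`` against per-class reference FASTAs.

    ``refs`` maps class name -> ``[(ref_id, sequence), ...]``.  Returns a
    mapping tag sequence -> :class:`AnnotationRecord`; unmatched tags get
    category ``unannotated``.  Classification is independent of tag order.
    """
    unknown = set(refs) - set(STRUCTURAL_CLASSES)
    if unknown:
        raise ConfigurationError(f"unknown structural classes: {sorted(unknown)}")
    for cls_name, entries in refs.items():
        if not entries:
            raise ConfigurationError(f"empty reference set for class {cls_name!r}")
    indexes = [(cls_name, _ClassIndex(refs[cls_name])) for cls_name in precedence if cls_name in refs]

    records: dict[str, AnnotationRecord] = {}
    for seq in table.sequences():
        category, evidence = "unannotated", None
        for cls_name, index in indexes:
            hit = index.match(seq)
            if hit is not None:
                category, evidence = cls_name, hit
                break
        records[seq] = AnnotationRecord(seq, category, evidence)
    return records


def summary_counts(
    records: Mapping[str, AnnotationRecord],
    table: TagTable,
    libraries: Sequence[Library],
) -> pd.DataFrame:
    """Per-library read counts per structural class, plus totals.

    Rows: the four structural classes, ``unannotated`` and ``Total reads``;
    columns: library ids.  Per library the class counts plus unannotated
    equal the total.
    """
    lib_ids = [l.id for l in libraries]
    counts = {cls: {lib: 0 for lib in lib_ids} for cls in STRUCTURAL_CLASSES + ("unannotated",)}
    totals = {lib: 0 for lib in lib_ids}
    for tag in table:
        cat = records[tag.sequence].category
        row = cat if cat in counts else "unannotated"
        for lib, n in tag.counts.items():
            counts[row][lib] += n
            totals[lib] += n
    frame = pd.DataFrame(counts).T[lib_ids]
    frame.loc["Total reads"] = [totals[lib] for lib in lib_ids]
    frame.index.name = "Small RNA"
    return frame


def format_summary(summary: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Render the summary as ``count(percent%)`` strings for the summary report."""
    totals = summary.loc["Total reads"]
    out = summary.copy().astype(object)
    for row in summary.index:
        if row == "Total reads":
            out.loc[row] = [str(int(v)) for v in summary.loc[row]]
            continue
        cells = []
        for lib in summary.columns:
            n = int(summary.loc[row, lib])
            pct = 100.0 * n / totals[lib] if totals[lib] else 0.0
            cells.append(f"{n}({pct:.{decimals}f}%)")
        out.loc[row] = cells
    return out
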