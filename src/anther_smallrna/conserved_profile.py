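"""Conserved miRNA family assignment and family-level abundance profiles.

Family assignment follows a two-tier reference rule: tags are first tested
against the species-specific mature/precursor references; only tags left
unassigned are then tested against the all-plant references.  A tag matches
a mature reference with at most ``max_mismatch`` substitutions and at most
2 nt of 5'/3' end offset, or by lying exactly within a precursor.  The best
(fewest-mismatch) match wins; ties are broken lexicographically by family
name.  Family names are normalized to family level (``ghr-miR156a`` ->
``miR156``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .io import read_fasta
from .preprocess import Library, TagTable

#: sequences longer than this are treated as precursors, not matures
MATURE_MAX_LEN = 30

_FAMILY_RE = re.compile(r"(?:^|-)?(mir|let)-?(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class MirnaRef:
    name: str
    family: str
    sequence: str
    is_precursor: bool


def family_name(ref_name: str) -> str | None:
    """Normalize a miRBase-style name to its family (strip species prefix
    and letter/number suffixes): ``ghr-miR156a`` -> ``miR156``."""
    m = _FAMILY_RE.search(ref_name)
    if not m:
        return None
    kind, num = m.groups()
    prefix = "let" if kind.lower() == "let" else "miR"
    return f"{prefix}{int(num)}"


def load_mirbase_fasta(path) -> list[MirnaRef]:
    """Load a mature+precursor FASTA with miRBase-style headers.

    Entries longer than ``MATURE_MAX_LEN`` nt are treated as precursors.
    Entries whose name yields no family are skipped.
    """
    refs = []
    for name, seq in read_fasta(path):
        fam = family_name(name)
        if fam is None:
            continue
        refs.append(MirnaRef(name, fam, seq, is_precursor=len(seq) > MATURE_MAX_LEN))
    return refs


def _match_mature(tag: str, mature: str, max_mismatch: int, max_end_offset: int) -> int | None:
    """Substitution count of the best end-anchored alignment, or None.

    The tag start may sit within ``max_end_offset`` nt of the mature start,
    and likewise for the ends; substitutions are counted over the overlap.
    """
    best = None
    for shift in range(-max_end_offset, max_end_offset + 1):
        off3 = (shift + len(tag)) - len(mature)
        if abs(off3) > max_end_offset:
            continue
        lo = max(0, shift)
        hi = min(len(mature), shift + len(tag))
        if hi - lo < len(tag) - 2 * max_end_offset:
            continue
        mm = sum(1 for i in range(lo, hi) if tag[i - shift] != mature[i])
        if mm <= max_mismatch and (best is None or mm < best):
            best = mm
    return best


def _best_family(
    tag: str, refs: Sequence[MirnaRef], max_mismatch: int, max_end_offset: int
) -> tuple[int, str] | None:
    best: tuple[int, str] | None = None
    for ref in refs:
        if ref.is_precursor:
            mm = 0 if tag in ref.sequence else None
        else:
            mm = _match_mature(tag, ref.sequence, max_mismatch, max_end_offset)
        if mm is None:
            continue
        cand = (mm, ref.family)
        if best is None or cand < best:
            best = cand
    return best


def assign_families(
    sequences: Iterable[str],
    species_refs: Sequence[MirnaRef],
    plant_refs: Sequence[MirnaRef] = (),
    *,
    max_mismatch: int = 2,
    max_end_offset: int = 2,
) -> dict[str, str]:
    """Two-tier family assignment; returns ``{tag sequence: family}``.

    Tier 2 (``plant_refs``) is consulted only for tags unassigned at tier 1,
    so tier-1 assignments never depend on the tier-2 reference set.
    """
    if not species_refs and not plant_refs:
        raise ConfigurationError("no miRNA references supplied")
    if max_mismatch < 0:
        raise ConfigurationError("max_mismatch must be >= 0")
    out: dict[str, str] = {}
    for tag in sequences:
        hit = _best_family(tag, species_refs, max_mismatch, max_end_offset)
        if hit is None and plant_refs:
            hit = _best_family(tag, plant_refs, max_mismatch, max_end_offset)
        if hit is not None:
            out[tag] = hit[1]
    return out


@dataclass
class MirnaFamilyProfile:
    """Family-level aggregated counts and relative abundances."""

    family: str
    member_tags: set[str] = field(default_factory=set)
    counts: dict[str, int] = field(default_factory=dict)
    #: genotype -> family reads / all conserved-family reads of that genotype
    relative_abundance: dict[str, float] = field(default_factory=dict)
    #: genotype -> genotype family reads / (WT+GMS family reads)
    share_of_total: dict[str, float] = field(default_factory=dict)


def family_abundance(
    assignments: Mapping[str, str],
    table: TagTable,
    libraries: Sequence[Library],
) -> list[MirnaFamilyProfile]:
    """Aggregate per-family counts and compute the two percentage views."""
    lib_geno = {l.id: l.genotype for l in libraries}
    profiles: dict[str, MirnaFamilyProfile] = {}
    for tag in table:
        fam = assignments.get(tag.sequence)
        if fam is None:
            continue
        prof = profiles.setdefault(fam, MirnaFamilyProfile(fam))
        prof.member_tags.add(tag.sequence)
        for lib, n in tag.counts.items():
            prof.counts[lib] = prof.counts.get(lib, 0) + n

    geno_totals: dict[str, int] = {}
    fam_geno: dict[str, dict[str, int]] = {}
    for fam, prof in profiles.items():
        per_geno: dict[str, int] = {}
        for lib, n in prof.counts.items():
            g = lib_geno.get(lib, "WT")
            per_geno[g] = per_geno.get(g, 0) + n
            geno_totals[g] = geno_totals.get(g, 0) + n
        fam_geno[fam] = per_geno

    genotypes = sorted({l.genotype for l in libraries})
    for fam, prof in profiles.items():
        fam_total = sum(fam_geno[fam].values())
        for g in genotypes:
            n = fam_geno[fam].get(g, 0)
            prof.relative_abundance[g] = n / geno_totals[g] if geno_totals.get(g) else 0.0
            prof.share_of_total[g] = n / fam_total if fam_total else 0.0
    return sorted(profiles.values(), key=lambda p: p.family)


def family_frame(profiles: Sequence[MirnaFamilyProfile], libraries: Sequence[Library]) -> pd.DataFrame:
    lib_ids = [l.id for l in libraries]
    genotypes = sorted({l.genotype for l in libraries})
    rows = []
    for p in profiles:
        row = {"family": p.family, "n_tags": len(p.member_tags)}
        for lib in lib_ids:
            row[lib] = p.counts.get(lib, 0)
        for g in genotypes:
            row[f"rel_abundance_{g}"] = p.relative_abundance.get(g, 0.0)
            row[f"share_of_total_{g}"] = p.share_of_total.get(g, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def unique_mirna_sharing(
    sets: Mapping[str, set[str]], pair: tuple[str, str]
) -> tuple[float, float, float]:
    """Percentages (exclusive A, exclusive B, shared) of the pairwise union.

    The three values sum to 100 (up to float rounding).  Raises
    :class:`ConfigurationError` if either library is missing and
    ``ValueError`` if both sets are empty (the union is undefined).
    """
    lib_a, lib_b = pair
    for lib in pair:
        if lib not in sets:
            raise ConfigurationError(f"library {lib!r} not present")
    a, b = sets[lib_a], sets[lib_b]
    union = a | b
    if not union:
        raise ValueError("sharing undefined: both sets are empty")
    scale = 100.0 / len(union)
    return (len(a - b) * scale, len(b - a) * scale, len(a & b) * scale)
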