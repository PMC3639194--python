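"""Novel miRNA calling: transcript mapping, precursor windows, folding, and
hairpin/duplex/energy criteria.

The built-in folding backend is a deterministic base-pair-maximization
model, not a thermodynamic one: it maximizes the summed pair weights
GC/CG -3, AU/UA -2, GU/UG -1 kcal/mol over pseudoknot-free structures with
hairpin loops of at least 3 nt and no penalty terms.  Any callable with the
same ``fold(sequence) -> (dot_bracket, energy)`` contract (e.g. a ViennaRNA
wrapper) can be substituted wherever a ``fold_fn`` argument is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ParseError
from .seqs import encode, normalize, revcomp, to_rna

# pair weights indexed by base codes (A0 C1 G2 T3 N4); energy = -sum(weights)
_PAIR_W = np.zeros((5, 5), dtype=np.int64)
for _a, _b, _w in (("G", "C", 3), ("A", "T", 2), ("G", "T", 1)):
    _i, _j = "ACGTN".index(_a), "ACGTN".index(_b)
    _PAIR_W[_i, _j] = _PAIR_W[_j, _i] = _w

MIN_HAIRPIN_LOOP = 3


def fold(sequence: str, min_loop: int = MIN_HAIRPIN_LOOP) -> tuple[str, float]:
    """Fold ``sequence`` under the built-in pair-weight proxy.

    Returns ``(dot_bracket, energy)`` with energy in proxy kcal/mol
    (always <= 0).  Deterministic: ties are resolved by a fixed traceback
    order (pairing first, then leftmost split).
    """
    s = normalize(sequence)
    n = len(s)
    if n < 2:
        return "." * n, 0.0
    codes = encode(s)
    w = _PAIR_W[codes[:, None], codes[None, :]]
    # dp[i, j] = max total weight over substring i..j (inclusive)
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(1, n):
        i = np.arange(0, n - span)
        j = i + span
        best = dp[i + 1, j]  # i unpaired (split at k=i)
        for m in range(1, span):
            np.maximum(best, dp[i, i + m] + dp[i + m + 1, j], out=best)
        if span > min_loop:
            np.maximum(best, dp[i + 1, j - 1] + w[i, j], out=best)
        dp[i, j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= 0:
            continue
        if j - i > min_loop and w[i, j] > 0 and dp[i, j] == dp[i + 1, j - 1] + w[i, j]:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i, j):
            left = 0 if k == i else dp[i, k]
            if dp[i, j] == left + dp[k + 1, j]:
                if k > i:
                    stack.append((i, k))
                stack.append((k + 1, j))
                break
    return "".join(structure), float(-dp[0, n - 1])


def pair_partners(structure: str) -> list[int | None]:
    """Partner index per position of a dot-bracket string (None if unpaired)."""
    partners: list[int | None] = [None] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partners[i], partners[j] = j, i
    return partners


def map_tags(
    sequences: Sequence[str], transcripts: Mapping[str, str]
) -> list[tuple[str, str, str, int]]:
    """Exact-match tag hits on either strand of the transcripts.

    Returns ``(tag, transcript_id, strand, start)`` tuples with 1-based
    inclusive start coordinates on the sense strand; all occurrences are
    reported.
    """
    hits = []
    for tag in sequences:
        probes = {"+": tag, "-": revcomp(tag)}
        for tid, tseq in transcripts.items():
            for strand, probe in probes.items():
                start = tseq.find(probe)
                while start >= 0:
                    hits.append((tag, tid, strand, start + 1))
                    start = tseq.find(probe, start + 1)
    return hits


def extract_windows(
    hit: tuple[str, str, str, int],
    transcripts: Mapping[str, str],
    up: int = 20,
    down: int = 220,
    min_len: int = 50,
) -> list[tuple[str, int, int]]:
    """Candidate precursor windows around a mapped tag.

    Two windows are produced per hit -- mature near the 5' end (short
    upstream flank, long downstream flank) and mature near the 3' end --
    truncated at transcript bounds; windows shorter than ``min_len`` are
    dropped.  Returns ``(window_sequence, mature_offset, window_start)``
    where ``mature_offset`` is the 0-based position of the tag within the
    window and ``window_start`` the 1-based window start on the strand of
    the hit.
    """
    tag, tid, strand, start = hit
    tseq = transcripts[tid]
    if strand == "-":
        tseq = revcomp(tseq)
        start = len(tseq) - (start + len(tag) - 1) + 1
    s0 = start - 1  # 0-based mature start
    windows = []
    for flank_up, flank_down in ((up, down), (down, up)):
        lo = max(0, s0 - flank_up)
        hi = min(len(tseq), s0 + len(tag) + flank_down)
        if hi - lo >= min_len:
            windows.append((tseq[lo:hi], s0 - lo, lo + 1))
    return windows


@dataclass
class HairpinCriteria:
    """Acceptance thresholds for :func:`evaluate_hairpin` (all configurable;
    the energy floor is consistent with the smallest-magnitude fold energy
    printed for an accepted novel miRNA, -18.33 proxy kcal/mol)."""

    max_energy: float = -18.0
    max_unpaired_mature: int = 4
    max_bulge_asymmetry: int = 2
    #: mature bases tolerated pairing outside the dominant arm (stray pairs)
    max_offside: int = 2
    min_precursor: int = 50
    max_precursor: int = 300


@dataclass
class HairpinCandidate:
    """A candidate precursor with structure, arms, energy and flags."""

    tag: str
    transcript: str | None
    mature_start: int  # 1-based within the precursor window
    precursor: str
    structure: str
    energy: float
    arm: str | None  # "5p" / "3p" / None when undetermined
    star_coordinates: tuple[int, int] | None
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return bool(self.flags) and all(self.flags.values())


def evaluate_hairpin(
    window: str,
    mature_offset: int,
    mature_len: int,
    criteria: HairpinCriteria | None = None,
    fold_fn: Callable[[str], tuple[str, float]] = fold,
    transcript: str | None = None,
) -> HairpinCandidate:
    """Fold a candidate window and apply the hairpin acceptance criteria.

    Accepted iff (a) the mature lies wholly within one arm and does not
    span the terminal loop, (b) the mature:star duplex leaves at most
    ``max_unpaired_mature`` mature bases unpaired (the 2-nt 3' overhang of
    Dicer geometry excluded) with bulge asymmetry <= ``max_bulge_asymmetry``,
    and (c) folding energy <= ``max_energy``.
    """
    crit = criteria or HairpinCriteria()
    window = normalize(window)
    structure, energy = fold_fn(window)
    partners = pair_partners(structure)
    m0, m1 = mature_offset, mature_offset + mature_len - 1  # inclusive, 0-based

    self_pairs = 0
    left: list[tuple[int, int]] = []
    right: list[tuple[int, int]] = []
    for i in range(m0, m1 + 1):
        p = partners[i]
        if p is None:
            continue
        if m0 <= p <= m1:
            self_pairs += 1
        elif p < m0:
            left.append((i, p))
        else:
            right.append((i, p))

    if len(right) >= len(left):
        dominant, minor, arm = right, left, "5p"
    else:
        dominant, minor, arm = left, right, "3p"
    offside = len(minor) + self_pairs

    mature_in_one_arm = bool(dominant) and offside <= crit.max_offside
    not_spanning_loop = self_pairs == 0 and len(minor) <= crit.max_offside

    # duplex geometry against the dominant arm; the mature's two 3'-terminal
    # bases are the expected Dicer overhang and are not required to pair
    duplex_positions = [(i, p) for i, p in dominant if i <= m1 - 2]
    unpaired = (mature_len - 2) - len(duplex_positions)
    max_asym = 0
    ordered = sorted(duplex_positions)
    for (i_a, p_a), (i_b, p_b) in zip(ordered, ordered[1:]):
        gap_m = i_b - i_a - 1
        gap_s = abs(p_a - p_b) - 1
        max_asym = max(max_asym, abs(gap_m - gap_s))
    duplex_ok = (
        bool(duplex_positions)
        and unpaired <= crit.max_unpaired_mature
        and max_asym <= crit.max_bulge_asymmetry
    )

    star: tuple[int, int] | None = None
    if dominant:
        ps = [p for _, p in dominant]
        star = (min(ps) + 1, min(max(ps) + 2, len(window) - 1) + 1)  # 1-based

    flags = {
        "mature_in_one_arm": mature_in_one_arm,
        "not_spanning_loop": not_spanning_loop,
        "duplex_ok": duplex_ok,
        "energy_ok": energy <= crit.max_energy,
    }
    return HairpinCandidate(
        tag=window[m0 : m1 + 1],
        transcript=transcript,
        mature_start=m0 + 1,
        precursor=window,
        structure=structure,
        energy=energy,
        arm=arm if dominant else None,
        star_coordinates=star,
        flags=flags,
    )


def find_hairpins(
    tag: str,
    transcripts: Mapping[str, str],
    criteria: HairpinCriteria | None = None,
    up: int = 20,
    down: int = 220,
    fold_fn: Callable[[str], tuple[str, float]] = fold,
    scales: Sequence[tuple[int, int]] | None = None,
) -> HairpinCandidate | None:
    """Map a tag, evaluate all candidate windows, keep the best per tag.

    Windows are evaluated at several flank scales (a long precursor window
    and a tight one; the whole-window fold of a long flank can mask a
    perfectly valid local stem).  Best = accepted first, then lowest
    energy.  Returns None when the tag does not map or no window reaches
    the minimum window length.
    """
    crit = criteria or HairpinCriteria()
    if scales is None:
        scales = ((up, down), (20, 80))
    best: HairpinCandidate | None = None
    for hit in map_tags([tag], transcripts):
        seen: set[tuple[str, int]] = set()
        windows = []
        for s_up, s_down in scales:
            for win in extract_windows(
                hit, transcripts, up=s_up, down=s_down, min_len=crit.min_precursor
            ):
                key = (win[0], win[1])
                if key not in seen:
                    seen.add(key)
                    windows.append(win)
        for window, offset, _ in windows:
            if len(window) > crit.max_precursor:
                window = window[: crit.max_precursor]
                if offset + len(tag) > len(window):
                    continue
            cand = evaluate_hairpin(window, offset, len(tag), crit, fold_fn, transcript=hit[1])
            if best is None or (cand.accepted, -cand.energy) > (best.accepted, -best.energy):
                best = cand
    return best


# ---------------------------------------------------------------------------
# published novel-miRNA table

_NAME_RE = re.compile(r"^(Mar-[FS]-\d)-m\d+$")


@dataclass(frozen=True)
class NovelMirnaRecord:
    name: str
    library: str
    count: int
    sequence: str  # RNA alphabet, as published
    fold_energy: float


def table2_fixture_path():
    """Path of the shipped novel-miRNA table fixture."""
    return resources.files("anther_smallrna") / "fixtures" / "table2_novel_mirnas.tsv"


def load_novel_table(path=None) -> list[NovelMirnaRecord]:
    """Load a novel-miRNA table (name, count, sequence, fold energy).

    The library is inferred from the record-name prefix
    (``Mar-F-1-m0001`` -> ``Mar-F-1``).  Duplicated names and malformed
    rows raise :class:`ParseError` naming the offending line.
    """
    path = table2_fixture_path() if path is None else path
    records: list[NovelMirnaRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.replace("−", "-").strip()
            if not line or line.lower().startswith("name"):
                continue
            fields = [f.strip() for f in re.split(r"[\t,]+", line)]
            if len(fields) != 4:
                raise ParseError(f"line {lineno}: expected 4 fields, got {len(fields)}")
            name, count_s, seq, energy_s = fields
            m = _NAME_RE.match(name)
            if not m:
                raise ParseError(f"line {lineno}: malformed record name {name!r}")
            if name in seen:
                raise ParseError(f"line {lineno}: duplicated record name {name!r}")
            try:
                count = int(count_s)
                energy = float(energy_s)
                rna = to_rna(normalize(seq))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if count < 1:
                raise ParseError(f"line {lineno}: count must be positive")
            seen.add(name)
            records.append(NovelMirnaRecord(name, m.group(1), count, rna, energy))
    return records


def records_by_library(records: Sequence[NovelMirnaRecord]) -> dict[str, list[NovelMirnaRecord]]:
    groups: dict[str, list[NovelMirnaRecord]] = {}
    for rec in records:
        groups.setdefault(rec.library, []).append(rec)
    return groups
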