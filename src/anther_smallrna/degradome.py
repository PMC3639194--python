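"""Degradome (PARE) cleavage-target identification.

miRNA:target duplexes are scored with penalties mismatch 1.0, G:U wobble
0.5 and single-nucleotide gap 1.0, doubled at miRNA positions 2-13 counted
from the miRNA 5' end; at most one gap is allowed.  Candidate sites are
every target window on the sense strand whose best alignment scores at
most ``max_score`` (default 4).  A site becomes a cleavage call when a
degradome signature 5' end falls exactly on the target nucleotide paired
to miRNA position 10 (canonical slicing between positions 10 and 11) or
position 11; the canonical position is reported.  Signature abundances are
normalized as TP10M = raw / (total genome match - structural) * 1e7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqs import encode, normalize

PEN_MISMATCH = 1.0
PEN_GU = 0.5
PEN_GAP = 1.0
#: 1-based inclusive miRNA positions where penalties are doubled
CORE_REGION = (2, 13)

# penalty lookup indexed by (mirna base code, target base code); N never pairs
_PEN = np.full((5, 5), PEN_MISMATCH)
for _m, _t in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PEN["ACGTN".index(_m), "ACGTN".index(_t)] = 0.0
for _m, _t in (("G", "T"), ("T", "G")):
    _PEN["ACGTN".index(_m), "ACGTN".index(_t)] = PEN_GU


def _multipliers(length: int) -> np.ndarray:
    mult = np.ones(length)
    lo, hi = CORE_REGION
    mult[lo - 1 : hi] = 2.0
    return mult


def _state(mirna_base: str, target_base: str) -> str:
    pen = _PEN["ACGTN".index(mirna_base), "ACGTN".index(target_base)]
    return "match" if pen == 0 else ("GU" if pen == PEN_GU else "mismatch")


@dataclass
class DuplexAlignment:
    """A miRNA:target alignment over miRNA positions 1..L (5'->3').

    ``states`` holds one of match/mismatch/GU/gap per miRNA position;
    ``target_bulge`` is the transcript coordinate of a bulged (unpaired)
    target base when the single allowed gap sits on the target side.
    Coordinates are 1-based inclusive on the sense strand.
    """

    mirna: str
    transcript: str | None
    start: int
    end: int
    states: tuple[str, ...]
    target_bulge: int | None
    score: float

    def partner_positions(self) -> list[int | None]:
        """Transcript coordinate paired to each miRNA position (1..L)."""
        out: list[int | None] = []
        pos = self.end
        for state in self.states:
            if self.target_bulge is not None and pos == self.target_bulge:
                pos -= 1
            if state == "gap":
                out.append(None)
            else:
                out.append(pos)
                pos -= 1
        return out

    def cleavage_position(self, mirna_position: int = 10) -> int | None:
        partners = self.partner_positions()
        if 1 <= mirna_position <= len(partners):
            return partners[mirna_position - 1]
        return None


@dataclass
class DegradomeSignature:
    """A 20-21 nt degradome 5'-end pile-up position on a transcript."""

    transcript: str
    position: int  # 1-based 5'-end coordinate
    length: int
    raw: int
    tp10m: float = 0.0
    hit_number: int = 1


@dataclass
class CleavageCall:
    mirna: str
    transcript: str
    cleavage_position: int
    duplex: DuplexAlignment
    raw: int
    tp10m: float
    category: int
    matched_position: int = 10  # 10 (canonical) or 11


# ---------------------------------------------------------------------------
# duplex scoring


def _alignment_states(
    mir: str, segment: str, gap_pos: int | None, bulge_offset: int | None
) -> tuple[tuple[str, ...], float]:
    """States and score for one explicit alignment configuration.

    ``gap_pos`` is the 1-based miRNA position left unpaired (segment length
    L-1); ``bulge_offset`` is the 0-based offset of the skipped target base
    counted from the segment 3' end (segment length L+1).
    """
    L = len(mir)
    mult = _multipliers(L)
    states: list[str] = []
    score = 0.0
    t = len(segment) - 1  # segment index aligned next, walking 3'->5'
    skipped = len(segment) - 1 - bulge_offset if bulge_offset is not None else None
    for i in range(1, L + 1):
        if skipped is not None and t == skipped:
            p = min(i, L)
            score += PEN_GAP * (2.0 if CORE_REGION[0] <= p <= CORE_REGION[1] else 1.0)
            t -= 1
        if gap_pos is not None and i == gap_pos:
            states.append("gap")
            score += PEN_GAP * mult[i - 1]
            continue
        base_t = segment[t]
        states.append(_state(mir[i - 1], base_t))
        score += _PEN["ACGTN".index(mir[i - 1]), "ACGTN".index(base_t)] * mult[i - 1]
        t -= 1
    if skipped is not None and t == skipped:  # bulge below the last miRNA base
        score += PEN_GAP * (2.0 if CORE_REGION[0] <= L <= CORE_REGION[1] else 1.0)
    return tuple(states), score


def score_duplex(
    mirna: str,
    target_segment: str,
    *,
    transcript: str | None = None,
    start: int = 1,
) -> DuplexAlignment:
    """Best alignment of ``mirna`` against one target segment.

    Segment length L yields the ungapped alignment; L-1 the best single
    miRNA-side gap; L+1 the best single target-side bulge.  A perfect
    complement scores 0.  Raises ``ValueError`` for segments shorter than
    L-1 (or longer than L+1, which would need more than one gap).
    """
    mir = normalize(mirna)
    if not 18 <= len(mir) <= 26:
        raise ValueError(f"miRNA length must be 18-26 nt (got {len(mir)})")
    seg = normalize(target_segment)
    L, n = len(mir), len(seg)
    if n < L - 1:
        raise ValueError(f"target segment shorter than miRNA-1 ({n} < {L - 1})")
    if n > L + 1:
        raise ValueError("at most one gap is allowed (segment too long)")

    end = start + n - 1
    best: DuplexAlignment | None = None
    if n == L:
        states, score = _alignment_states(mir, seg, None, None)
        best = DuplexAlignment(mir, transcript, start, end, states, None, score)
    elif n == L - 1:
        for g in range(1, L + 1):
            states, score = _alignment_states(mir, seg, g, None)
            if best is None or score < best.score:
                best = DuplexAlignment(mir, transcript, start, end, states, None, score)
    else:  # n == L + 1
        for k in range(0, L + 1):
            states, score = _alignment_states(mir, seg, None, k)
            if best is None or score < best.score:
                bulge_coord = end - k
                best = DuplexAlignment(mir, transcript, start, end, states, bulge_coord, score)
    assert best is not None
    return best


def _scan_transcript(
    mir_codes: np.ndarray, t_codes: np.ndarray
) -> list[tuple[int, int, float]]:
    """Vectorized best score per (start, segment length) on one transcript.

    Returns ``(start0, segment_length, score)`` for every window; gapped
    classes are minimized over gap placements.
    """
    L = len(mir_codes)
    n = len(t_codes)
    mult = _multipliers(L)
    out: list[tuple[int, int, float]] = []
    rev = mir_codes[::-1]

    if n >= L:  # ungapped: mirna position i pairs t[s + L - i]
        win = np.lib.stride_tricks.sliding_window_view(t_codes, L)
        scores = (_PEN[rev[None, :], win] * mult[::-1][None, :]).sum(axis=1)
        out.extend((s, L, float(v)) for s, v in enumerate(scores))

    if n >= L - 1:  # one miRNA base bulged; segment length L-1
        win = np.lib.stride_tricks.sliding_window_view(t_codes, L - 1)
        best = np.full(win.shape[0], np.inf)
        for g in range(1, L + 1):
            keep = np.delete(np.arange(L), g - 1)
            m_del = mir_codes[keep][::-1]
            mult_del = mult[keep][::-1]
            gap_pen = PEN_GAP * mult[g - 1]
            np.minimum(best, (_PEN[m_del[None, :], win] * mult_del[None, :]).sum(axis=1) + gap_pen, out=best)
        out.extend((s, L - 1, float(v)) for s, v in enumerate(best))

    if n >= L + 1:  # one target base bulged; segment length L+1
        win = np.lib.stride_tricks.sliding_window_view(t_codes, L + 1)
        best = np.full(win.shape[0], np.inf)
        for k in range(0, L + 1):
            cols = np.delete(np.arange(L + 1), L - k)  # drop k-th from segment 3' end
            aligned = win[:, cols]
            gap_mult = 2.0 if CORE_REGION[0] <= min(k + 1, L) <= CORE_REGION[1] else 1.0
            np.minimum(
                best,
                (_PEN[rev[None, :], aligned] * mult[::-1][None, :]).sum(axis=1) + PEN_GAP * gap_mult,
                out=best,
            )
        out.extend((s, L + 1, float(v)) for s, v in enumerate(best))
    return out


def find_candidate_sites(
    mirna: str,
    transcripts: Mapping[str, str],
    max_score: float = 4.0,
) -> list[DuplexAlignment]:
    """Exhaustively scan every sense-strand window of every transcript.

    For each (transcript, start, segment length) the best alignment
    (ungapped or single-gap) is computed; alignments scoring at most
    ``max_score`` are returned sorted by (score, transcript, position).
    """
    mir = normalize(mirna)
    mir_codes = encode(mir)
    hits: list[DuplexAlignment] = []
    for tid in sorted(transcripts):
        t_norm = normalize(transcripts[tid])
        t_codes = encode(t_norm)
        for s0, seg_len, score in _scan_transcript(mir_codes, t_codes):
            if score <= max_score:
                segment = t_norm[s0 : s0 + seg_len]
                aln = score_duplex(mir, segment, transcript=tid, start=s0 + 1)
                hits.append(aln)
    hits.sort(key=lambda a: (a.score, a.transcript, a.start))
    return hits


# ---------------------------------------------------------------------------
# degradome signatures


def build_kmer_index(
    transcripts: Mapping[str, str], lengths: tuple[int, ...] = (20, 21)
) -> dict[str, list[tuple[str, int]]]:
    """Exact-match index: k-mer -> [(transcript, 1-based position), ...]."""
    index: dict[str, list[tuple[str, int]]] = {}
    for tid in sorted(transcripts):
        seq = normalize(transcripts[tid])
        for k in lengths:
            for i in range(0, len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((tid, i + 1))
    return index


def map_degradome(
    reads: Iterable[str],
    transcripts: Mapping[str, str],
    lengths: tuple[int, ...] = (20, 21),
    index: dict[str, list[tuple[str, int]]] | None = None,
) -> list[DegradomeSignature]:
    """Exact sense-strand mapping of 20-21 nt degradome reads.

    Produces one signature per (transcript, position, length) with summed
    raw counts; ``hit_number`` is the number of distinct transcripts the
    read sequence matches.  The full raw count is credited at every locus
    of a multi-mapping read (no fractional splitting).
    """
    if index is None:
        index = build_kmer_index(transcripts, lengths)

    raw: dict[tuple[str, int, int], int] = {}
    hitno: dict[tuple[str, int, int], int] = {}
    for read in reads:
        seq = normalize(read)
        if len(seq) not in lengths:
            continue
        loci = index.get(seq)
        if not loci:
            continue
        n_transcripts = len({tid for tid, _ in loci})
        for tid, pos in loci:
            key = (tid, pos, len(seq))
            raw[key] = raw.get(key, 0) + 1
            hitno[key] = n_transcripts
    return [
        DegradomeSignature(tid, pos, length, count, hit_number=hitno[(tid, pos, length)])
        for (tid, pos, length), count in sorted(raw.items())
    ]


def tp10m(raw: int, total_genome_match: int, structural: int) -> float:
    """TP10M = raw / (total genome match - structural) * 10,000,000."""
    denom = total_genome_match - structural
    if denom <= 0:
        raise ValueError("total genome match must exceed structural count")
    return raw / denom * 10_000_000


def normalize_signatures(
    signatures: Sequence[DegradomeSignature], total_genome_match: int, structural: int
) -> list[DegradomeSignature]:
    """Fill ``tp10m`` on every signature (in place; returns the list)."""
    for sig in signatures:
        sig.tp10m = tp10m(sig.raw, total_genome_match, structural)
    return list(signatures)


def _position_raw(signatures: Iterable[DegradomeSignature]) -> dict[str, dict[int, int]]:
    by_transcript: dict[str, dict[int, int]] = {}
    for sig in signatures:
        pos = by_transcript.setdefault(sig.transcript, {})
        pos[sig.position] = pos.get(sig.position, 0) + sig.raw
    return by_transcript


def classify_category(site_raw: int, position_raws: Mapping[int, int]) -> int:
    """CleaveLand-style peak category of a site on its transcript.

    0: unique transcript maximum; 1: equals a shared maximum; 2: above the
    median; 3: at or below the median with raw > 1; 4: a single read.  The
    median is computed over positions carrying at least one signature, and
    the rules are applied in that order.
    """
    values = list(position_raws.values())
    if not values:
        raise ValueError("transcript has no signatures")
    mx = max(values)
    if site_raw == mx:
        return 0 if values.count(mx) == 1 else 1
    if site_raw > median(values):
        return 2
    return 3 if site_raw > 1 else 4


def call_cleavage(
    sites: Sequence[DuplexAlignment],
    signatures: Sequence[DegradomeSignature],
    accept_positions: tuple[int, ...] = (10, 11),
) -> list[CleavageCall]:
    """Intersect candidate duplex sites with degradome signature 5' ends.

    A site yields a call iff a signature 5' end falls exactly on the target
    nucleotide paired to miRNA position 10 (canonical) or 11; the canonical
    position is reported.  Calls are deduplicated per (miRNA, transcript,
    cleavage position) keeping the lowest-scoring duplex, and sorted by
    (category, descending TP10M).
    """
    by_pos: dict[tuple[str, int], tuple[int, float]] = {}
    for sig in signatures:
        key = (sig.transcript, sig.position)
        r, t = by_pos.get(key, (0, 0.0))
        by_pos[key] = (r + sig.raw, t + sig.tp10m)
    raw_by_transcript = _position_raw(signatures)

    calls: dict[tuple[str, str, int], CleavageCall] = {}
    for site in sites:
        if site.transcript is None:
            continue
        partners = site.partner_positions()
        matched = None
        for p in accept_positions:
            coord = partners[p - 1] if p <= len(partners) else None
            if coord is not None and (site.transcript, coord) in by_pos:
                matched = (p, coord)
                break
        if matched is None:
            continue
        mpos, coord = matched
        canonical = partners[9] if partners[9] is not None else coord
        raw, tpm = by_pos[(site.transcript, coord)]
        category = classify_category(raw, raw_by_transcript[site.transcript])
        key = (site.mirna, site.transcript, canonical)
        call = CleavageCall(
            mirna=site.mirna,
            transcript=site.transcript,
            cleavage_position=canonical,
            duplex=site,
            raw=raw,
            tp10m=tpm,
            category=category,
            matched_position=mpos,
        )
        if key not in calls or site.score < calls[key].duplex.score:
            calls[key] = call
    return sorted(calls.values(), key=lambda c: (c.category, -c.tp10m, c.transcript, c.cleavage_position))


def tplot_table(
    transcript: str,
    signatures: Sequence[DegradomeSignature],
    calls: Sequence[CleavageCall] = (),
) -> pd.DataFrame:
    """Per-position abundance table for a t-plot, with call positions flagged."""
    rows: dict[int, dict] = {}
    for sig in signatures:
        if sig.transcript != transcript:
            continue
        row = rows.setdefault(sig.position, {"position": sig.position, "raw": 0, "tp10m": 0.0})
        row["raw"] += sig.raw
        row["tp10m"] += sig.tp10m
    call_positions = {c.cleavage_position for c in calls if c.transcript == transcript}
    for pos, row in rows.items():
        row["is_cleavage_site"] = pos in call_positions
    frame = pd.DataFrame(sorted(rows.values(), key=lambda r: r["position"]))
    if frame.empty:
        frame = pd.DataFrame(columns=["position", "raw", "tp10m", "is_cleavage_site"])
    return frame


def calls_frame(calls: Sequence[CleavageCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": c.mirna,
                "transcript": c.transcript,
                "cleavage_position": c.cleavage_position,
                "score": c.duplex.score,
                "raw": c.raw,
                "tp10m": c.tp10m,
                "category": c.category,
                "matched_position": c.matched_position,
            }
            for c in calls
        ]
    )
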