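"""Independent brute-force duplex-scoring oracle used by the tests.

Explicitly enumerates every alignment (ungapped, every single miRNA-side
gap, every single target-side bulge) of every window and scores it with a
scalar penalty walk -- deliberately sharing no code with the vectorized
scanner it checks.
"""

_ORACLE_PEN = {}
for _m in "ACGT":
    for _t in "ACGT":
        _ORACLE_PEN[(_m, _t)] = 1.0
for _m, _t in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _ORACLE_PEN[(_m, _t)] = 0.0
for _m, _t in (("G", "T"), ("T", "G")):
    _ORACLE_PEN[(_m, _t)] = 0.5


def _mult(pos):
    return 2.0 if 2 <= pos <= 13 else 1.0


def oracle_score(mir, seg):
    """Best score over all allowed alignments of one segment (<= 1 gap)."""
    L, n = len(mir), len(seg)
    best = None

    def consider(score):
        nonlocal best
        if best is None or score < best:
            best = score

    if n == L:
        consider(sum(_ORACLE_PEN[(mir[i], seg[L - 1 - i])] * _mult(i + 1) for i in range(L)))
    elif n == L - 1:
        for g in range(1, L + 1):
            score = _mult(g)  # gap penalty
            t = n - 1
            for i in range(1, L + 1):
                if i == g:
                    continue
                score += _ORACLE_PEN[(mir[i - 1], seg[t])] * _mult(i)
                t -= 1
            consider(score)
    elif n == L + 1:
        for k in range(0, L + 1):  # k-th target base from the segment 3' end bulged
            skipped = n - 1 - k
            score = _mult(min(k + 1, L))
            t = n - 1
            for i in range(1, L + 1):
                if t == skipped:
                    t -= 1
                score += _ORACLE_PEN[(mir[i - 1], seg[t])] * _mult(i)
                t -= 1
            consider(score)
    return best


def oracle_sites(mir, transcripts, max_score=4.0):
    """Exhaustive window enumeration: {(transcript, start, seg_len, score)}."""
    out = set()
    for tid, seq in transcripts.items():
        n = len(seq)
        for s in range(n):
            for seg_len in (len(mir) - 1, len(mir), len(mir) + 1):
                if s + seg_len > n:
                    continue
                score = oracle_score(mir, seq[s : s + seg_len])
                if score is not None and score <= max_score:
                    out.add((tid, s + 1, seg_len, score))
    return out
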