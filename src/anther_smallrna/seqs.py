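"""Nucleotide alphabet helpers shared across the toolkit.

Sequences are stored internally as uppercase DNA (``ACGT``); RNA input
(``U``) is accepted everywhere and converted on the way in.  :func:`to_rna`
converts back for miRNA-facing output tables.
"""

from __future__ import annotations

import numpy as np

_RNA2DNA = str.maketrans("Uu", "Tt")
_COMP = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")

#: integer codes used by the folding and duplex-scoring kernels
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_CODES.items():
    _ENCODE_LUT[ord(_b)] = _c


class AlphabetError(ValueError):
    """A sequence contains characters outside ACGTUN (case-insensitive)."""


def normalize(seq: str) -> str:
    """Return ``seq`` as uppercase DNA, converting U to T.

    Raises :class:`AlphabetError` on anything outside ACGTUN.
    """
    s = seq.strip().translate(_RNA2DNA).upper()
    if not _VALID.issuperset(s):
        bad = sorted(set(s) - _VALID)
        raise AlphabetError(f"invalid nucleotide(s) {bad!r} in sequence")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of a normalized DNA sequence."""
    return seq.translate(_COMP)[::-1]


def to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def encode(seq: str) -> np.ndarray:
    """Encode a normalized sequence as a uint8 code array (A0 C1 G2 T3 N4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
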