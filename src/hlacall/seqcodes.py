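"""Compact integer encoding of nucleotide sequences.

Alphabet: A, C, G, T, ``-`` (alignment gap), ``N`` (unknown base).
Codes 0-3 are the four bases; anything >= 4 is "not a callable base".
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT-N"
A, C, G, T, GAP, UNKNOWN = range(6)
N_BASES = 4

_CODE = {ch: i for i, ch in enumerate(ALPHABET)}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-",
    # IUPAC degenerate codes
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

#: IUPAC degenerate code -> set of plain bases it matches
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the allowed alphabet."""


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string as a uint8 code array.

    Raises :class:`SequenceAlphabetError` naming the first illegal character
    and its 0-based position.
    """
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        code = _CODE.get(ch)
        if code is None:
            raise SequenceAlphabetError(
                f"illegal character {ch!r} at position {i}"
            )
        out[i] = code
    return out


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def revcomp(seq: str) -> str:
    """Reverse complement; accepts IUPAC degenerate codes and gaps."""
    try:
        return "".join(_COMPLEMENT[ch] for ch in reversed(seq.upper()))
    except KeyError as exc:
        raise SequenceAlphabetError(f"cannot complement {exc.args[0]!r}") from None


def iupac_mismatches(pattern: str, seq: str, limit: int | None = None) -> int:
    """Number of positions where ``seq`` is incompatible with IUPAC ``pattern``.

    ``seq`` is compared position-by-position against ``pattern`` (both the
    same length is not required: comparison runs over ``len(pattern)``; a
    too-short ``seq`` counts the overhang as mismatches). Stops early once
    ``limit`` mismatches are exceeded, returning ``limit + 1``.
    """
    n = len(pattern)
    mism = 0
    for i in range(n):
        if i >= len(seq) or seq[i] not in IUPAC.get(pattern[i], frozenset()):
            mism += 1
            if limit is not None and mism > limit:
                return mism
    return mism
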