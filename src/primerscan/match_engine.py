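"""Locate primers in target sequences with IUPAC classes and a mismatch budget.

A primer position written as a degenerate IUPAC code accepts any base in
that code's expansion; a target position matches a primer position iff the
target character is literally a member of the primer position's class.
Degenerate characters in the *target* therefore never match by
set-intersection (a target ``N`` against primer class ``{A,G}`` costs one
mismatch) — quality control surfaces such characters upstream.

The mismatch model is substitution-only: every hit has exactly the primer's
length, so positions stay well-defined. All orderings are deterministic
(ascending start, then end); there is no randomness anywhere in the engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "IUPAC_CODES",
    "MatchHit",
    "AmpliconHit",
    "iupac_class",
    "reverse_complement",
    "find_primer_hits",
    "find_amplicons",
]

#: Expansion of each of the 15 IUPAC nucleotide codes into plain bases.
IUPAC_CODES: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT: dict[str, str] = {
    "A": "T",
    "C": "G",
    "G": "C",
    "T": "A",
    "R": "Y",
    "Y": "R",
    "S": "S",
    "W": "W",
    "K": "M",
    "M": "K",
    "B": "V",
    "V": "B",
    "D": "H",
    "H": "D",
    "N": "N",
}

# Bit encoding A=1 C=2 G=4 T=8; a class mask ORs the bits of its members.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CLASS_MASK = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_CODES.items()
}

# Lookup table: ASCII byte -> base bit (0 for anything that is not A/C/G/T,
# so degenerate or foreign target characters mismatch every class).
_TARGET_LUT = np.zeros(256, dtype=np.uint8)
for _b, _bit in _BASE_BIT.items():
    _TARGET_LUT[ord(_b)] = _bit


def iupac_class(code: str) -> frozenset:
    """Return the set of plain bases accepted by one IUPAC code.

    >>> sorted(iupac_class("R"))
    ['A', 'G']
    """
    try:
        return frozenset(IUPAC_CODES[code.upper()])
    except KeyError:
        raise ValueError(f"unknown IUPAC nucleotide code: {code!r}") from None


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H; S,W,N fixed)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    except KeyError:
        bad = next(c for c in seq.upper() if c not in _COMPLEMENT)
        raise ValueError(f"invalid IUPAC character in sequence: {bad!r}") from None


@dataclass(frozen=True)
class MatchHit:
    """One located primer occurrence (0-based, half-open coordinates)."""

    target_id: str
    start: int
    end: int
    mismatches: int
    matched_seq: str


@dataclass(frozen=True)
class AmpliconHit:
    """A forward/reverse hit combination spanning both primer footprints."""

    target_id: str
    fwd: MatchHit
    rev: MatchHit
    amplicon_seq: str

    @property
    def amp_start(self) -> int:
        return self.fwd.start

    @property
    def amp_end(self) -> int:
        return self.rev.end

    @property
    def length(self) -> int:
        return self.rev.end - self.fwd.start


def _primer_masks(primer_seq: str) -> np.ndarray:
    try:
        return np.array([_CLASS_MASK[c] for c in primer_seq], dtype=np.uint8)
    except KeyError:
        bad = next(c for c in primer_seq if c not in _CLASS_MASK)
        raise ValueError(f"invalid IUPAC character in primer: {bad!r}") from None


def find_primer_hits(
    primer_seq: str,
    target_seq: str,
    max_mismatches: int = 0,
    target_id: str = "",
) -> list[MatchHit]:
    """Return every window of the target matching the primer.

    A window at offset ``i`` matches iff the number of positions ``j`` with
    ``target[i+j]`` outside ``iupac_class(primer[j])`` is at most
    ``max_mismatches``. Overlapping hits are all reported, in ascending
    offset order.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    primer = primer_seq.upper()
    target = target_seq.upper()
    m, n = len(primer), len(target)
    if m == 0:
        raise ValueError("primer sequence is empty")
    if n < m:
        return []

    masks = _primer_masks(primer)
    tbits = _TARGET_LUT[np.frombuffer(target.encode("ascii", "replace"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(tbits, m)
    mm_counts = ((windows & masks) == 0).sum(axis=1)
    offsets = np.nonzero(mm_counts <= max_mismatches)[0]

    return [
        MatchHit(
            target_id=target_id,
            start=int(i),
            end=int(i) + m,
            mismatches=int(mm_counts[i]),
            matched_seq=target[i : i + m],
        )
        for i in offsets
    ]


def find_amplicons(
    fwd_seq: str,
    rev_seq: str,
    target_seq: str,
    max_mismatches: int = 0,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
    rc_reverse: bool = False,
    target_id: str = "",
) -> list[AmpliconHit]:
    """Enumerate all valid forward x reverse hit combinations on one target.

    The reverse primer is searched literally as written (primers are assumed
    to be given in amplification orientation); with ``rc_reverse=True`` it is
    reverse-complemented first. A combination is valid when the forward
    footprint ends at or before the reverse footprint starts and the total
    span — forward start through reverse end, both footprints included —
    satisfies the length bounds.

    Results are sorted by (span start, span length); the first element is the
    representative used for per-sequence summaries.
    """
    rev_search = reverse_complement(rev_seq) if rc_reverse else rev_seq.upper()
    target = target_seq.upper()
    fwd_hits = find_primer_hits(fwd_seq, target, max_mismatches, target_id)
    if not fwd_hits:
        return []
    rev_hits = find_primer_hits(rev_search, target, max_mismatches, target_id)
    if not rev_hits:
        return []

    lo = min_len if min_len is not None else 0
    hi = max_len if max_len is not None else None
    out: list[AmpliconHit] = []
    for f in fwd_hits:
        for r in rev_hits:
            if r.start < f.end:
                continue
            length = r.end - f.start
            if length < lo or (hi is not None and length > hi):
                continue
            out.append(
                AmpliconHit(
                    target_id=target_id,
                    fwd=f,
                    rev=r,
                    amplicon_seq=target[f.start : r.end],
                )
            )
    out.sort(key=lambda a: (a.amp_start, a.length))
    return out
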