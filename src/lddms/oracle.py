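"""Pattern-driven exhaustive (l,d1,d2)-motif search — the ground truth.

An (l,d1,d2)-motif is an l-mer that occurs within hamming distance d1 of
some window of *every* input sequence (the (l,d1)-condition) and within
distance d2 of some window of *at least one* sequence (the
(l,d2)-condition).  The exhaustive search enumerates all |Sigma|^l
patterns in lexicographic order and tests both conditions directly; it is
exponential in l and exists as the correctness oracle for the
sample-driven algorithms in :mod:`lddms.search`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dist
from .alphabet import Alphabet
from .hamming import MotifSet, hamming
from .sequences import SequenceSet, windows

__all__ = [
    "LDDMSParams",
    "min_distance",
    "satisfies_d1_condition",
    "satisfies_d2_condition",
    "brute_force_search",
    "DEFAULT_MAX_PATTERNS",
]

DEFAULT_MAX_PATTERNS = 10_000_000


@dataclass(frozen=True)
class LDDMSParams:
    """Search parameters (l, d1, d2).

    The model assumes the tight radius is strictly smaller than the
    global one, ``0 <= d2 < d1 <= l``.  With ``relaxed=True`` the
    constraint ``d2 < d1`` is lifted; the (l,d2)-condition is then implied
    by the (l,d1)-condition and the problem degrades to plain
    (l,d1)-motif search (LDMS).
    """

    l: int
    d1: int
    d2: int
    relaxed: bool = False

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("motif length l must be positive")
        if not 0 <= self.d1 <= self.l:
            raise ValueError(f"d1={self.d1} must satisfy 0 <= d1 <= l={self.l}")
        if not 0 <= self.d2 <= self.l:
            raise ValueError(f"d2={self.d2} must satisfy 0 <= d2 <= l={self.l}")
        if not self.relaxed and self.d2 >= self.d1:
            raise ValueError(
                f"the model assumes d2 < d1 (got d2={self.d2}, d1={self.d1}); "
                f"pass relaxed=True to degrade to plain (l,d1)-motif search"
            )


def min_distance(x: str, seq: str) -> int:
    """Smallest hamming distance between ``x`` and any window of ``seq``."""
    l = len(x)
    if len(seq) < l:
        raise ValueError(f"sequence length {len(seq)} is shorter than l={l}")
    return min(hamming(x, v) for v in windows(seq, l))


def satisfies_d1_condition(x: str, seqs: SequenceSet, d1: int) -> bool:
    """True iff ``x`` is within ``d1`` of some window of *every* sequence."""
    return all(min_distance(x, s) <= d1 for s in seqs.residues)


def satisfies_d2_condition(x: str, seqs: SequenceSet, d2: int) -> bool:
    """True iff ``x`` is within ``d2`` of some window of *some* sequence."""
    return any(min_distance(x, s) <= d2 for s in seqs.residues)


def _pattern_chunk(start: int, stop: int, sigma: int, l: int) -> np.ndarray:
    """Rank-encoded patterns ``start..stop-1`` in lexicographic order.

    Pattern ``t`` is the base-``sigma`` expansion of ``t`` with the most
    significant digit first — a vectorized odometer over Sigma^l.
    """
    t = np.arange(start, stop, dtype=np.int64)
    out = np.empty((t.shape[0], l), dtype=np.uint8)
    for pos in range(l - 1, -1, -1):
        out[:, pos] = t % sigma
        t //= sigma
    return out


def brute_force_search(
    seqs: SequenceSet,
    params: LDDMSParams,
    alphabet: Alphabet | None = None,
    max_patterns: int = DEFAULT_MAX_PATTERNS,
) -> MotifSet:
    """Exhaustive (l,d1,d2)-motif search over all |Sigma|^l patterns.

    Patterns are streamed in lexicographic chunks, so the output is
    sorted by construction.  Refuses to run when |Sigma|^l exceeds
    ``max_patterns``.
    """
    alphabet = alphabet or seqs.alphabet
    sigma, l = alphabet.size, params.l
    total = sigma**l
    if total > max_patterns:
        raise ValueError(
            f"|Sigma|^l = {total} patterns exceeds the guard of {max_patterns}; "
            f"use the sample-driven algorithms (lddms1/lddms2/lddms3) or raise "
            f"max_patterns"
        )
    if min(seqs.lengths) < l:
        raise ValueError("every sequence must be at least l long")
    win_list = _dist.all_window_codes(seqs, l)
    found: list[str] = []
    step = 65_536
    for a in range(0, total, step):
        cands = _pattern_chunk(a, min(a + step, total), sigma, l)
        ok = _dist.filter_d1(cands, win_list, params.d1)
        if ok.any():
            survivors = cands[ok]
            ok2 = _dist.satisfies_any_d2(survivors, win_list, params.d2)
            found.extend(alphabet.decode_rows(survivors[ok2]))
    return MotifSet._from_sorted(found)
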