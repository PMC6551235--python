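"""Vectorized hamming-distance kernels shared by the search algorithms.

All kernels work on rank-encoded ``uint8`` matrices: a candidate set is
``(N, l)``, a sequence's windows are ``(W, l)``.  Broadcast comparisons
are chunked so intermediate boolean tensors stay within a few tens of MB.
"""

from __future__ import annotations

import numpy as np

from .alphabet import Alphabet
from .sequences import SequenceSet

_CHUNK_CELLS = 16_000_000  # cap on W * l * chunk rows per broadcast


def window_codes(seq: str, l: int, alphabet: Alphabet) -> np.ndarray:
    """Rank-encoded windows of one sequence, shape ``(len(seq)-l+1, l)``."""
    codes = alphabet.encode(seq)
    if l > codes.shape[0]:
        raise ValueError(f"window length {l} exceeds sequence length {codes.shape[0]}")
    return np.lib.stride_tricks.sliding_window_view(codes, l).copy()


def all_window_codes(seqs: SequenceSet, l: int) -> list[np.ndarray]:
    return [window_codes(s, l, seqs.alphabet) for s in seqs.residues]


def min_dists(cands: np.ndarray, wins: np.ndarray) -> np.ndarray:
    """Minimum hamming distance from each candidate row to any window row."""
    n, l = cands.shape
    w = wins.shape[0]
    out = np.empty(n, dtype=np.int32)
    step = max(1, _CHUNK_CELLS // max(1, w * l))
    for a in range(0, n, step):
        b = min(a + step, n)
        d = (cands[a:b, None, :] != wins[None, :, :]).sum(axis=2)
        out[a:b] = d.min(axis=1)
    return out


def filter_d1(
    cands: np.ndarray, win_list: list[np.ndarray], d1: int, skip: int | None = None
) -> np.ndarray:
    """Boolean mask of candidates within ``d1`` of a window of *every*
    sequence.

    Sequences are checked one at a time against the shrinking survivor
    set, cheapest-rejection-first in input order.  ``skip`` marks a
    sequence known to be satisfied by construction (e.g. the sequence the
    candidates' neighborhoods were generated from).
    """
    alive = np.ones(cands.shape[0], dtype=bool)
    for q, wins in enumerate(win_list):
        if q == skip or not alive.any():
            continue
        idx = np.nonzero(alive)[0]
        ok = min_dists(cands[idx], wins) <= d1
        alive[idx[~ok]] = False
    return alive


def satisfies_any_d2(cands: np.ndarray, win_list: list[np.ndarray], d2: int) -> np.ndarray:
    """Boolean mask of candidates within ``d2`` of a window of *some*
    sequence."""
    sat = np.zeros(cands.shape[0], dtype=bool)
    for wins in win_list:
        idx = np.nonzero(~sat)[0]
        if idx.size == 0:
            break
        sat[idx] = min_dists(cands[idx], wins) <= d2
    return sat
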