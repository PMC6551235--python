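"""The three exact sample-driven (l,d1,d2)-motif search algorithms.

* :func:`lddms1` — solve the plain (l,d1)-motif problem first (any exact
  LDMS solver works; :func:`ldms_solve` below is self-contained), then
  keep the motifs that also satisfy the (l,d2)-condition.
* :func:`lddms2` — generate the d2-neighborhood of every window of every
  sequence (each such l-mer satisfies the (l,d2)-condition by
  construction), radix-sort and deduplicate, then keep the candidates
  that satisfy the (l,d1)-condition.
* :func:`lddms3` — like lddms2, but the d2-neighborhood of each window u
  (from sequence i) is explored as a depth-first tree while maintaining

      delta(x, i, I) = max_{q != i} min_{v window of seq q} Hd(v, x),

  the worst-sequence distance of the current node x.  delta changes by at
  most one per tree edge, which yields branch-and-bound rules (see
  :func:`prune_decision`): a node with delta <= d1 is output; a node
  whose deficit delta - d1 exceeds the remaining depth budget d2 - h is
  pruned with its whole subtree; when the deficit exactly equals the
  budget (or falls short of it by one) only children that decrease delta
  (or at least do not increase it) can still reach a motif.

All three return the identical sorted motif set; they differ only in how
much of the candidate space they touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import _dist
from .alphabet import Alphabet
from .hamming import MotifSet, _dedupe_sorted_codes, _mutation_templates, _radix_sort_codes
from .oracle import LDDMSParams
from .sequences import SequenceSet

__all__ = [
    "ldms_solve",
    "lddms1",
    "lddms2",
    "lddms3",
    "delta",
    "delta_child_update",
    "root_node",
    "prune_decision",
    "NeighborhoodNode",
    "PruneVerdict",
    "DEFAULT_MAX_CANDIDATES",
]

DEFAULT_MAX_CANDIDATES = 50_000_000


# ---------------------------------------------------------------------------
# candidate generation


def _bulk_neighborhood_codes(
    win_codes: np.ndarray, d: int, sigma: int
) -> np.ndarray:
    """Stacked d-neighborhood members of every window row.

    For each radius k <= d the mutation templates (position choices and
    character offsets) are root-independent, so one fancy-indexing pass
    expands all windows at once.
    """
    w, l = win_codes.shape
    parts = []
    for k in range(d + 1):
        pos, off = _mutation_templates(l, k, sigma)
        kk = pos.shape[0]
        block = np.repeat(win_codes, kk, axis=0)
        if k:
            tiled_pos = np.tile(pos, (w, 1))
            tiled_off = np.tile(off, (w, 1))
            rows = np.arange(w * kk)[:, None]
            block[rows, tiled_pos] = (block[rows, tiled_pos] + tiled_off) % sigma
        parts.append(block)
    return np.concatenate(parts, axis=0)


def _sorted_unique(codes: np.ndarray, sigma: int) -> np.ndarray:
    return _dedupe_sorted_codes(_radix_sort_codes(codes, sigma))


def ldms_solve(
    seqs: SequenceSet, l: int, d: int, alphabet: Alphabet | None = None
) -> MotifSet:
    """Exact plain (l,d)-motif search (LDMS).

    Any (l,d)-motif is within distance d of some window of every
    sequence — in particular of the reference sequence 0 — so the union
    of d-neighborhoods of sequence 0's windows is a complete candidate
    set; candidates are then screened against the remaining sequences.
    """
    alphabet = alphabet or seqs.alphabet
    if not 0 <= d <= l:
        raise ValueError(f"radius d={d} must satisfy 0 <= d <= l={l}")
    if min(seqs.lengths) < l:
        raise ValueError("every sequence must be at least l long")
    win_list = _dist.all_window_codes(seqs, l)
    cands = _sorted_unique(
        _bulk_neighborhood_codes(win_list[0], d, alphabet.size), alphabet.size
    )
    ok = _dist.filter_d1(cands, win_list, d, skip=0)
    return MotifSet._from_sorted(alphabet.decode_rows(cands[ok]))


def lddms1(
    seqs: SequenceSet,
    params: LDDMSParams,
    alphabet: Alphabet | None = None,
    counters: dict | None = None,
) -> MotifSet:
    """LDMS-then-filter: all (l,d1)-motifs, filtered by the
    (l,d2)-condition.

    ``counters``, if given, receives ``c1`` — the size of the
    intermediate (l,d1)-motif set.
    """
    alphabet = alphabet or seqs.alphabet
    c1 = ldms_solve(seqs, params.l, params.d1, alphabet)
    if counters is not None:
        counters["c1"] = len(c1)
    if params.d2 >= params.d1:
        return c1  # the (l,d2)-condition is implied by the (l,d1)-condition
    win_list = _dist.all_window_codes(seqs, params.l)
    codes = np.stack([alphabet.encode(x) for x in c1]) if len(c1) else np.zeros(
        (0, params.l), dtype=np.uint8
    )
    ok = _dist.satisfies_any_d2(codes, win_list, params.d2)
    return MotifSet._from_sorted([x for x, keep in zip(c1, ok) if keep])


def lddms2(
    seqs: SequenceSet,
    params: LDDMSParams,
    alphabet: Alphabet | None = None,
    max_candidates: int = DEFAULT_MAX_CANDIDATES,
    counters: dict | None = None,
) -> MotifSet:
    """Neighborhood-generation-then-check.

    The union of d2-neighborhoods of all n(m-l+1) windows is exactly the
    set of l-mers satisfying the (l,d2)-condition; after radix sort and
    deduplication each candidate is screened against the
    (l,d1)-condition.  ``counters`` receives ``c2`` — the deduplicated
    candidate count.
    """
    alphabet = alphabet or seqs.alphabet
    l = params.l
    if min(seqs.lengths) < l:
        raise ValueError("every sequence must be at least l long")
    win_list = _dist.all_window_codes(seqs, l)
    total_windows = sum(w.shape[0] for w in win_list)
    from .hamming import neighborhood_size

    est = total_windows * neighborhood_size(alphabet.size, l, params.d2)
    if est > max_candidates:
        raise ValueError(
            f"estimated candidate count {est} exceeds the guard of "
            f"{max_candidates}; use lddms3 or raise max_candidates"
        )
    blocks = [
        _bulk_neighborhood_codes(w, params.d2, alphabet.size) for w in win_list
    ]
    cands = _sorted_unique(np.concatenate(blocks, axis=0), alphabet.size)
    if counters is not None:
        counters["c2"] = cands.shape[0]
    ok = _dist.filter_d1(cands, win_list, params.d1)
    return MotifSet._from_sorted(alphabet.decode_rows(cands[ok]))


# ---------------------------------------------------------------------------
# delta state and the pruned tree traversal (LDDMS3)


class _Workspace:
    """Precomputed window matrices for fast distance-state updates.

    Windows of all sequences are concatenated into one ``(T, l)`` matrix;
    a node's distance state is the length-T vector of hamming distances
    from the node's l-mer to every window.  Mutating one motif position
    shifts each window's distance by -1, 0 or +1 depending on whether the
    window matched the old and/or the new character there, so a child's
    state costs O(T) = O(nm) to derive from its parent's.
    """

    def __init__(self, seqs: SequenceSet, l: int):
        self.alphabet = seqs.alphabet
        self.n = seqs.n
        self.win_list = _dist.all_window_codes(seqs, l)
        self.winchars = np.concatenate(self.win_list, axis=0)
        counts = [w.shape[0] for w in self.win_list]
        self.seg_starts = np.concatenate(([0], np.cumsum(counts)[:-1])).astype(np.int64)
        # eq[c][:, p] == True iff window character at offset p equals symbol c
        self.eq = [self.winchars == c for c in range(self.alphabet.size)]

    def root_dist(self, code: np.ndarray) -> np.ndarray:
        return (self.winchars != code).sum(axis=1).astype(np.int16)

    def child_dist(
        self, dist: np.ndarray, p: int, old: int, new: int
    ) -> np.ndarray:
        return dist + self.eq[old][:, p] - self.eq[new][:, p]

    def seq_mins(self, dist: np.ndarray) -> np.ndarray:
        return np.minimum.reduceat(dist, self.seg_starts)

    def delta(self, dist: np.ndarray, i: int) -> int:
        mins = self.seq_mins(dist)
        mins[i] = -1
        return int(mins.max())


@dataclass
class NeighborhoodNode:
    """A node of the d2-neighborhood tree of a window of sequence ``source_index``.

    ``dist_state`` concatenates, per sequence in order, the hamming
    distances from ``x`` to every window of that sequence (the source
    sequence's block is kept for completeness; ``delta`` ignores it).
    ``h`` is the node's level, equal to ``hamming(x, root)``; ``mutated``
    lists the positions changed relative to the root, in ascending order.
    """

    x: str
    h: int
    source_index: int
    dist_state: np.ndarray = field(repr=False)
    delta: int = 0
    mutated: tuple[int, ...] = ()
    _ws: "_Workspace | None" = field(default=None, repr=False)

    def distances_to(self, q: int) -> np.ndarray:
        """Distance vector from ``x`` to each window of sequence ``q``."""
        ws = self._require_ws()
        start = int(ws.seg_starts[q])
        stop = int(ws.seg_starts[q + 1]) if q + 1 < ws.n else ws.winchars.shape[0]
        return self.dist_state[start:stop]

    def _require_ws(self) -> "_Workspace":
        if self._ws is None:
            raise ValueError("node is detached from its sequence workspace")
        return self._ws


def root_node(
    u: str, i: int, seqs: SequenceSet, _ws: _Workspace | None = None
) -> NeighborhoodNode:
    """Root of the neighborhood tree for window ``u`` of sequence ``i``."""
    if seqs.n < 2:
        raise ValueError("delta state requires at least two sequences")
    if not 0 <= i < seqs.n:
        raise ValueError(f"sequence index {i} out of range")
    ws = _ws or _Workspace(seqs, len(u))
    dist = ws.root_dist(seqs.alphabet.encode(u))
    return NeighborhoodNode(
        x=u, h=0, source_index=i, dist_state=dist, delta=ws.delta(dist, i), _ws=ws
    )


def delta(x: str, i: int, seqs: SequenceSet) -> int:
    """delta(x, i, I): worst-sequence minimum distance, excluding sequence i.

    The maximum over all sequences q != i of the minimum hamming distance
    between ``x`` and any window of sequence q.  Undefined for a single
    sequence (the index set is empty).
    """
    from .oracle import min_distance

    if seqs.n < 2:
        raise ValueError("delta(x, i, I) is undefined for a single sequence")
    if not 0 <= i < seqs.n:
        raise ValueError(f"sequence index {i} out of range")
    return max(min_distance(x, s) for q, s in enumerate(seqs.residues) if q != i)


def delta_child_update(
    parent: NeighborhoodNode,
    position: int,
    new_char: str,
    seqs: SequenceSet,
) -> NeighborhoodNode:
    """Derive a child node by mutating one not-yet-mutated position.

    The child's distance state is obtained incrementally in O(nm): each
    window's distance moves by ``(window matched old char) - (window
    matches new char)``.  ``new_char`` must differ from the parent's
    (equivalently the root's) character at ``position``.
    """
    ws = parent._require_ws()
    alphabet = seqs.alphabet
    if position in parent.mutated:
        raise ValueError(f"position {position} was already mutated on this path")
    if not 0 <= position < len(parent.x):
        raise ValueError(f"position {position} out of range")
    old = alphabet.index(parent.x[position])
    new = alphabet.index(new_char)
    if new == old:
        raise ValueError("child must change the character at the mutated position")
    dist = ws.child_dist(parent.dist_state, position, old, new)
    x = parent.x[:position] + new_char + parent.x[position + 1 :]
    return NeighborhoodNode(
        x=x,
        h=parent.h + 1,
        source_index=parent.source_index,
        dist_state=dist,
        delta=ws.delta(dist, parent.source_index),
        mutated=tuple(sorted(parent.mutated + (position,))),
        _ws=ws,
    )


class PruneVerdict(Enum):
    """Branch-and-bound verdict for a neighborhood-tree node."""

    OUTPUT_AND_DESCEND = "output_and_descend"
    DESCEND_ALL = "descend_all"
    DESCEND_DECREASING_ONLY = "descend_decreasing_only"
    DESCEND_NONINCREASING_ONLY = "descend_nonincreasing_only"
    PRUNE = "prune"


def prune_decision(delta_val: int, h: int, params: LDDMSParams) -> PruneVerdict:
    """Classify a node with worst-sequence distance ``delta_val`` at level ``h``.

    delta changes by at most one per tree edge and at most ``d2 - h``
    edges remain, so a node whose deficit ``delta_val - d1`` exceeds the
    remaining budget can never reach a motif below it; a deficit exactly
    equal to the budget requires every further step to decrease delta,
    and a deficit one short of it tolerates no increasing step.
    """
    deficit = delta_val - params.d1
    budget = params.d2 - h
    if deficit <= 0:
        return PruneVerdict.OUTPUT_AND_DESCEND
    if deficit > budget:
        return PruneVerdict.PRUNE
    if deficit == budget:
        return PruneVerdict.DESCEND_DECREASING_ONLY
    if deficit == budget - 1:
        return PruneVerdict.DESCEND_NONINCREASING_ONLY
    return PruneVerdict.DESCEND_ALL


def lddms3(
    seqs: SequenceSet,
    params: LDDMSParams,
    alphabet: Alphabet | None = None,
    pruning: bool = True,
) -> MotifSet:
    """Pruned depth-first search of every window's d2-neighborhood tree.

    For each window u of each sequence i, traverse u's d2-neighborhood
    tree maintaining the distance state incrementally; every node with
    delta <= d1 is collected (its (l,d1)-condition holds for q != i by
    delta, and for q = i because the node is within d2 < d1 of u; its
    (l,d2)-condition holds by construction).  With ``pruning=False`` the
    branch-and-bound rules are disabled and every node is tested — used
    to validate the pruning's soundness.

    Requires the strict regime d2 < d1; with a single sequence the
    problem collapses to lddms2 semantics.
    """
    alphabet = alphabet or seqs.alphabet
    if params.d2 >= params.d1:
        raise ValueError(
            "lddms3 requires d2 < d1 (the automatic (l,d1)-condition for the "
            "source sequence needs it); use lddms1 for the relaxed problem"
        )
    if seqs.n == 1:
        return lddms2(seqs, params, alphabet)
    if min(seqs.lengths) < params.l:
        raise ValueError("every sequence must be at least l long")

    ws = _Workspace(seqs, params.l)
    sigma, l = alphabet.size, params.l
    out_codes: list[bytes] = []
    seen_roots: set[bytes] = set()

    for i in range(seqs.n):
        wins = ws.win_list[i]
        for w in range(wins.shape[0]):
            root = wins[w]
            key = root.tobytes()
            if key in seen_roots:
                continue  # identical window => identical tree
            seen_roots.add(key)
            code = root.copy()
            dist = ws.root_dist(code)
            _traverse(ws, i, code, dist, ws.delta(dist, i), 0, -1,
                      root, params, pruning, out_codes)

    if not out_codes:
        return MotifSet._from_sorted(())
    codes = np.frombuffer(b"".join(out_codes), dtype=np.uint8).reshape(-1, l)
    return MotifSet._from_sorted(
        alphabet.decode_rows(_sorted_unique(codes, sigma))
    )


def _traverse(
    ws: _Workspace,
    i: int,
    code: np.ndarray,
    dist: np.ndarray,
    delta_val: int,
    h: int,
    last_pos: int,
    root: np.ndarray,
    params: LDDMSParams,
    pruning: bool,
    out: list[bytes],
) -> None:
    if pruning:
        verdict = prune_decision(delta_val, h, params)
    else:
        verdict = (
            PruneVerdict.OUTPUT_AND_DESCEND
            if delta_val <= params.d1
            else PruneVerdict.DESCEND_ALL
        )
    if verdict is PruneVerdict.OUTPUT_AND_DESCEND:
        out.append(code.tobytes())
    if h == params.d2 or verdict is PruneVerdict.PRUNE:
        return
    sigma, l = ws.alphabet.size, params.l
    for p in range(last_pos + 1, l):
        old = int(root[p])
        eq_old = ws.eq[old][:, p]
        for new in range(sigma):
            if new == old:
                continue
            child_dist = (dist + eq_old - ws.eq[new][:, p]).astype(np.int16)
            child_delta = ws.delta(child_dist, i)
            if pruning:
                if (
                    verdict is PruneVerdict.DESCEND_DECREASING_ONLY
                    and child_delta != delta_val - 1
                ):
                    continue
                if (
                    verdict is PruneVerdict.DESCEND_NONINCREASING_ONLY
                    and child_delta > delta_val
                ):
                    continue
            code[p] = new
            _traverse(ws, i, code, child_dist, child_delta,
                      h + 1, p, root, params, pruning, out)
        code[p] = old
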