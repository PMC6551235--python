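"""Hamming-distance primitives on l-mers.

This module provides the combinatorial substrate of the motif search:
exact-distance ("friendhood") and at-most-distance ("neighborhood")
enumeration around an l-mer, the closed-form neighborhood size

    N(Sigma, l, d) = sum_{i=0}^{d} C(l, i) (|Sigma| - 1)^i,

a least-significant-position-first counting radix sort for deduplicating
large l-mer collections in O(total characters), the common-neighbor
criterion (two l-mers a, b admit a string within d_a of a and d_b of b
iff Hd(a, b) <= d_a + d_b), and a duplicate-free depth-first traversal of
the d-neighborhood tree.

Neighborhood tree
-----------------
The tree is rooted at an l-mer u; a node at level h is an l-mer at
hamming distance exactly h from u.  Duplicates are avoided by letting a
node's children mutate only positions strictly greater than the largest
position already mutated on the path from the root, and only to
characters that differ from the *root's* character at that position.
Every member of the d-neighborhood then appears exactly once, and the
level of a node equals its distance from the root.
"""

from __future__ import annotations

import enum
from functools import lru_cache
from math import comb
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .alphabet import DNA, Alphabet

__all__ = [
    "MotifSet",
    "hamming",
    "neighborhood",
    "friendhood",
    "neighborhood_size",
    "radix_sort_dedupe",
    "common_neighbor_exists",
    "neighborhood_tree_traverse",
    "TreeVerdict",
]


def hamming(u: str, v: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(u) != len(v):
        raise ValueError(f"length mismatch: {len(u)} vs {len(v)}")
    return sum(a != b for a, b in zip(u, v))


class MotifSet:
    """An immutable, duplicate-free collection of equal-length l-mers,
    kept in ascending lexicographic order under the alphabet's symbol
    order."""

    __slots__ = ("items", "_members")

    def __init__(self, items: Iterable[str], alphabet: Alphabet = DNA):
        key = alphabet.encode
        uniq = sorted(set(items), key=lambda s: key(s).tobytes())
        if uniq and len({len(s) for s in uniq}) != 1:
            raise ValueError("all motifs in a MotifSet must have equal length")
        self.items = tuple(uniq)
        self._members = frozenset(uniq)

    @classmethod
    def _from_sorted(cls, items: Sequence[str]) -> "MotifSet":
        """Trusted constructor for already-sorted, already-unique input."""
        obj = object.__new__(cls)
        obj.items = tuple(items)
        obj._members = frozenset(obj.items)
        return obj

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[str]:
        return iter(self.items)

    def __contains__(self, lmer: str) -> bool:
        return lmer in self._members

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MotifSet):
            return self.items == other.items
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.items)

    def __repr__(self) -> str:
        preview = ", ".join(self.items[:4]) + ("..." if len(self) > 4 else "")
        return f"MotifSet(n={len(self)}: {preview})"

    def as_set(self) -> frozenset[str]:
        return self._members

    def issuperset(self, other: Iterable[str]) -> bool:
        return self._members.issuperset(other)


def neighborhood_size(sigma: int, l: int, d: int) -> int:
    """Exact count of l-mers within hamming distance ``d`` of any fixed
    l-mer over an alphabet of size ``sigma``."""
    if sigma < 2:
        raise ValueError("alphabet size must be at least 2")
    if not 0 <= d <= l:
        raise ValueError(f"radius d={d} must satisfy 0 <= d <= l={l}")
    return sum(comb(l, i) * (sigma - 1) ** i for i in range(d + 1))


@lru_cache(maxsize=128)
def _mutation_templates(
    l: int, k: int, sigma: int
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and character offsets for all distance-``k`` mutants.

    Returns ``(pos, off)`` of shape ``(K, k)`` with
    ``K = C(l, k) * (sigma - 1) ** k``.  A mutant of root ``r`` is obtained
    by setting ``r[pos[j]] = (r[pos[j]] + off[j]) % sigma`` for each column
    ``j``; offsets in ``1..sigma-1`` guarantee every mutated character
    differs from the root's.  Templates are root-independent, so one table
    serves every window.
    """
    from itertools import combinations, product

    if k == 0:
        return np.zeros((1, 0), dtype=np.int64), np.zeros((1, 0), dtype=np.uint8)
    pos_list = []
    off_list = []
    offsets = list(product(range(1, sigma), repeat=k))
    for positions in combinations(range(l), k):
        for off in offsets:
            pos_list.append(positions)
            off_list.append(off)
    return np.array(pos_list, dtype=np.int64), np.array(off_list, dtype=np.uint8)


def _mutants_codes(root: np.ndarray, k: int, sigma: int) -> np.ndarray:
    """Rank-encoded l-mers at distance exactly ``k`` from ``root``."""
    l = root.shape[0]
    pos, off = _mutation_templates(l, k, sigma)
    out = np.broadcast_to(root, (pos.shape[0], l)).copy()
    rows = np.arange(pos.shape[0])[:, None]
    out[rows, pos] = (root[pos] + off) % sigma
    return out


def friendhood(u: str, d: int, alphabet: Alphabet = DNA) -> MotifSet:
    """All l-mers at hamming distance *exactly* ``d`` from ``u``."""
    root = alphabet.encode(u)
    if not 0 <= d <= root.shape[0]:
        raise ValueError(f"radius d={d} must satisfy 0 <= d <= l={root.shape[0]}")
    codes = _mutants_codes(root, d, alphabet.size)
    return radix_sort_dedupe(alphabet.decode_rows(codes), alphabet)


def neighborhood(u: str, d: int, alphabet: Alphabet = DNA) -> MotifSet:
    """All l-mers at hamming distance at most ``d`` from ``u``.

    The result is the disjoint union of the friendhoods of radii
    ``0..d``; its size equals :func:`neighborhood_size`.
    """
    root = alphabet.encode(u)
    if not 0 <= d <= root.shape[0]:
        raise ValueError(f"radius d={d} must satisfy 0 <= d <= l={root.shape[0]}")
    parts = [_mutants_codes(root, k, alphabet.size) for k in range(d + 1)]
    codes = np.concatenate(parts, axis=0)
    return radix_sort_dedupe(alphabet.decode_rows(codes), alphabet)


def _radix_sort_codes(codes: np.ndarray, sigma: int) -> np.ndarray:
    """Stable LSD radix sort of rank-encoded rows via counting passes."""
    n, l = codes.shape
    order = np.arange(n)
    occ = np.empty(n, dtype=np.int64)
    for pos in range(l - 1, -1, -1):
        col = codes[order, pos].astype(np.int64)
        counts = np.bincount(col, minlength=sigma)
        starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
        # occurrence index of each element within its symbol class keeps
        # the pass stable
        for s in range(sigma):
            mask = col == s
            occ[mask] = np.arange(int(counts[s]))
        new_order = np.empty(n, dtype=np.int64)
        new_order[starts[col] + occ] = order
        order = new_order
    return codes[order]


def _dedupe_sorted_codes(codes: np.ndarray) -> np.ndarray:
    if codes.shape[0] == 0:
        return codes
    keep = np.ones(codes.shape[0], dtype=bool)
    keep[1:] = np.any(codes[1:] != codes[:-1], axis=1)
    return codes[keep]


def radix_sort_dedupe(lmers: Sequence[str], alphabet: Alphabet = DNA) -> MotifSet:
    """Sort l-mers by alphabet order and drop duplicates.

    Uses a least-significant-position-first counting radix sort, so the
    cost is linear in the total number of characters (times the alphabet
    size for the stable occurrence counting).
    """
    lmers = list(lmers)
    if not lmers:
        return MotifSet._from_sorted(())
    if len({len(s) for s in lmers}) != 1:
        raise ValueError("radix sort requires l-mers of equal length")
    codes = np.stack([alphabet.encode(s) for s in lmers])
    out = _dedupe_sorted_codes(_radix_sort_codes(codes, alphabet.size))
    return MotifSet._from_sorted(alphabet.decode_rows(out))


def common_neighbor_exists(a: str, b: str, da: int, db: int) -> bool:
    """Whether some l-mer lies within ``da`` of ``a`` and ``db`` of ``b``.

    Equivalent to ``hamming(a, b) <= da + db``: the distance budget can be
    split along a shortest mutation path between the two l-mers.
    """
    return hamming(a, b) <= da + db


class TreeVerdict(enum.Enum):
    """Control returned by a neighborhood-tree visitor."""

    DESCEND = "descend"
    PRUNE = "prune"


#: A visitor receives (l-mer, level, mutated positions) and returns either a
#: TreeVerdict or a per-child predicate ``filter(child_lmer) -> bool``.
Visitor = Callable[[str, int, tuple[int, ...]], "TreeVerdict | Callable[[str], bool]"]


def neighborhood_tree_traverse(
    u: str, d: int, alphabet: Alphabet, visitor: Visitor
) -> None:
    """Depth-first traversal of the d-neighborhood tree rooted at ``u``.

    Every l-mer within distance ``d`` of ``u`` is visited exactly once;
    the level passed to the visitor equals its hamming distance from the
    root.  The visitor's verdict controls descent: ``TreeVerdict.DESCEND``
    explores all children, ``TreeVerdict.PRUNE`` skips the subtree, and a
    callable restricts descent to children for which it returns true.
    """
    root = alphabet.encode(u)
    l = root.shape[0]
    if not 0 <= d <= l:
        raise ValueError(f"radius d={d} must satisfy 0 <= d <= l={l}")
    chars = list(u)
    mutated: list[int] = []

    def rec(level: int, last_pos: int) -> None:
        verdict = visitor("".join(chars), level, tuple(mutated))
        if verdict is TreeVerdict.PRUNE or level == d:
            return
        child_ok = verdict if callable(verdict) else None
        for p in range(last_pos + 1, l):
            original = chars[p]
            for c in alphabet.symbols:
                if c == u[p]:
                    continue
                chars[p] = c
                if child_ok is None or child_ok("".join(chars)):
                    mutated.append(p)
                    rec(level + 1, p)
                    mutated.pop()
            chars[p] = original

    rec(0, -1)
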