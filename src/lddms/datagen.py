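"""Planted-instance benchmark generator.

A benchmark instance consists of n i.i.d.-uniform background sequences
of length m into which two related l-mers are embedded: M1 (in the first
ceil(n/2) sequences) and M2 (in the rest), where M2 is M1 mutated at
exactly q positions.  By the common-neighbor criterion, M1 and M2 share
neighbors within radius d2 of both iff q <= 2*d2, so q controls how many
(l,d1,d2)-motifs are guaranteed to exist: the conventional settings are
q = 0 when d2 = 0 (at least N(Sigma, l, d2) motifs) and q = 2*d2
otherwise (at least C(2*d2, d2) motifs, each obtained by switching
exactly d2 of the 2*d2 differing positions from M1's character to M2's).

Planting overwrites l consecutive background characters at a uniformly
chosen offset, so every sequence keeps length exactly m.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from math import comb

import numpy as np

from .alphabet import DNA, Alphabet
from .hamming import neighborhood_size
from .sequences import SequenceSet, write_fasta

__all__ = ["PlantedInstance", "generate_instance", "planted_motif_floor", "write_instance"]


@dataclass(frozen=True)
class PlantedInstance:
    """A generated benchmark: sequences plus the planting ground truth.

    The first ``ceil(n/2)`` sequences contain ``m1`` at their recorded
    offset, the remaining ``floor(n/2)`` contain ``m2``;
    ``hamming(m1, m2) == q`` exactly.
    """

    seqs: SequenceSet
    m1: str
    m2: str
    q: int
    positions: tuple[int, ...]
    seed: int

    @property
    def n_m1(self) -> int:
        """Number of sequences carrying m1."""
        return (self.seqs.n + 1) // 2


def generate_instance(
    n: int,
    m: int,
    l: int,
    q: int,
    alphabet: Alphabet = DNA,
    seed: int = 0,
) -> PlantedInstance:
    """Generate a planted (M1, M2, q) instance; reproducible from ``seed``.

    M1 is uniform over Sigma^l; M2 mutates a uniform q-subset of M1's
    positions, each to a uniformly chosen different character; the
    background is i.i.d. uniform; plant offsets are uniform on
    ``[0, m - l]``.
    """
    if n < 1:
        raise ValueError("need at least one sequence")
    if not 0 <= q <= l:
        raise ValueError(f"planted distance q={q} must satisfy 0 <= q <= l={l}")
    if l > m:
        raise ValueError(f"motif length l={l} exceeds sequence length m={m}")
    sigma = alphabet.size
    rng = np.random.default_rng(seed)

    m1_codes = rng.integers(0, sigma, size=l, dtype=np.uint8)
    mut_positions = np.sort(rng.choice(l, size=q, replace=False)) if q else np.array([], dtype=int)
    m2_codes = m1_codes.copy()
    for p in mut_positions:
        m2_codes[p] = (m1_codes[p] + rng.integers(1, sigma)) % sigma

    background = rng.integers(0, sigma, size=(n, m), dtype=np.uint8)
    offsets = rng.integers(0, m - l + 1, size=n)
    n_m1 = (n + 1) // 2
    records = []
    for i in range(n):
        row = background[i]
        planted = m1_codes if i < n_m1 else m2_codes
        row[offsets[i] : offsets[i] + l] = planted
        records.append((f"seq{i + 1}", alphabet.decode(row)))

    return PlantedInstance(
        seqs=SequenceSet(tuple(records), alphabet),
        m1=alphabet.decode(m1_codes),
        m2=alphabet.decode(m2_codes),
        q=q,
        positions=tuple(int(o) for o in offsets),
        seed=seed,
    )


def planted_motif_floor(q: int, d2: int, sigma: int, l: int) -> int:
    """Guaranteed minimum number of planted (l,d1,d2)-motifs for generous d1.

    For ``q = 0`` the whole d2-ball around the (single) planted l-mer
    qualifies: ``N(sigma, l, d2)`` motifs.  For ``q = 2*d2`` exactly
    ``C(2*d2, d2)`` l-mers spend the full budget on the differing
    positions, matching M1 on half of them and M2 on the other half.
    """
    if q == 0:
        return neighborhood_size(sigma, l, d2)
    if q == 2 * d2:
        return comb(2 * d2, d2)
    raise ValueError(
        f"no floor is defined for q={q}; supported settings are q=0 and q=2*d2"
    )


def write_instance(
    inst: PlantedInstance,
    fasta_path: str | os.PathLike,
    manifest_path: str | os.PathLike | None = None,
) -> None:
    """Write the instance as FASTA plus a plain-text ground-truth manifest."""
    write_fasta(inst.seqs, fasta_path)
    if manifest_path is None:
        return
    with open(manifest_path, "w") as fh:
        fh.write(f"m1\t{inst.m1}\n")
        fh.write(f"m2\t{inst.m2}\n")
        fh.write(f"q\t{inst.q}\n")
        fh.write(f"seed\t{inst.seed}\n")
        for (ident, _), off in zip(inst.seqs, inst.positions):
            fh.write(f"offset\t{ident}\t{off}\n")
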