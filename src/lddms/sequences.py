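"""FASTA input/output and windowed access to sequence sets.

The search algorithms operate on a :class:`SequenceSet`: an ordered list
of named residue strings validated against a fixed :class:`~lddms.alphabet.Alphabet`.
Sequences may have unequal lengths; every algorithm only requires that each
sequence is at least as long as the motif length l.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .alphabet import DNA, Alphabet

__all__ = ["SequenceSet", "read_fasta", "write_fasta", "windows"]

_WRAP = 70  # output line width


@dataclass(frozen=True)
class SequenceSet:
    """Ordered, alphabet-validated collection of named sequences.

    Attributes
    ----------
    records:
        ``(identifier, residues)`` pairs; residues are uppercase strings
        over ``alphabet``.
    alphabet:
        The alphabet the residues were validated against.
    """

    records: tuple[tuple[str, str], ...]
    alphabet: Alphabet = field(default=DNA)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a SequenceSet requires at least one sequence")
        object.__setattr__(self, "records", tuple((str(i), str(s)) for i, s in self.records))
        for ident, seq in self.records:
            for pos, ch in enumerate(seq):
                if ch not in self.alphabet:
                    raise ValueError(
                        f"record {ident!r}: character {ch!r} at position {pos} "
                        f"is not in the alphabet"
                    )

    @classmethod
    def from_strings(
        cls, residues: Sequence[str], alphabet: Alphabet = DNA
    ) -> "SequenceSet":
        """Build a set from bare strings, auto-naming records seq1, seq2, ..."""
        return cls(tuple((f"seq{i + 1}", s) for i, s in enumerate(residues)), alphabet)

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.records)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for _, s in self.records)

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    def __getitem__(self, q: int) -> str:
        return self.records[q][1]


def read_fasta(path: str | os.PathLike, alphabet: Alphabet = DNA) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Residues are uppercased before validation.  Raises ``ValueError`` on an
    empty file ("no records"), on text appearing before the first ``>``
    header (naming the line), or on residues outside the alphabet (naming
    the record and position).
    """
    with open(path) as handle:
        # SimpleFastaParser silently skips leading junk; detect it here so
        # the error can name the offending line.
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {line.strip()[:30]!r}"
                )
            break
        handle.seek(0)
        records = [
            (title.split()[0] if title.split() else title, seq.upper())
            for title, seq in SimpleFastaParser(handle)
        ]
    if not records:
        raise ValueError(f"{path}: no records")
    return SequenceSet(tuple(records), alphabet)


def write_fasta(seqs: SequenceSet, path: str | os.PathLike) -> None:
    """Write a :class:`SequenceSet` as FASTA with 70-column wrapping."""
    with open(path, "w") as handle:
        for ident, seq in seqs:
            handle.write(f">{ident}\n")
            for start in range(0, len(seq), _WRAP):
                handle.write(seq[start : start + _WRAP] + "\n")


def windows(seq: str, l: int) -> list[str]:
    """All length-``l`` substrings of ``seq``, left to right.

    Window ``i`` covers the half-open interval ``[i, i+l)``; there are
    exactly ``len(seq) - l + 1`` windows.
    """
    if l < 1:
        raise ValueError("window length must be at least 1")
    if l > len(seq):
        raise ValueError(
            f"window length {l} exceeds sequence length {len(seq)}"
        )
    return [seq[i : i + l] for i in range(len(seq) - l + 1)]
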