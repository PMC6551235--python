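"""Residue alphabets and rank encoding.

An :class:`Alphabet` fixes the set of admissible characters *and* their
order.  The order matters: it defines the lexicographic order used for
sorted motif output and the digit order of the radix sort, so two motif
sets are only comparable when produced under the same alphabet.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["Alphabet", "DNA", "PROTEIN"]


class Alphabet:
    """An ordered alphabet of distinct single characters.

    Parameters
    ----------
    symbols:
        The characters of the alphabet, in the order that defines
        lexicographic rank (e.g. ``"ACGT"``).
    """

    __slots__ = ("symbols", "_rank", "_lut", "_bytes")

    def __init__(self, symbols: str | Iterable[str]):
        syms = tuple(symbols)
        if len(syms) < 2:
            raise ValueError("alphabet must contain at least 2 symbols")
        if any(len(s) != 1 for s in syms):
            raise ValueError("alphabet symbols must be single characters")
        if len(set(syms)) != len(syms):
            raise ValueError("alphabet symbols must be distinct")
        self.symbols = syms
        self._rank = {c: i for i, c in enumerate(syms)}
        lut = np.full(256, 255, dtype=np.uint8)
        for i, c in enumerate(syms):
            lut[ord(c)] = i
        self._lut = lut
        self._bytes = np.frombuffer("".join(syms).encode("ascii"), dtype=np.uint8)

    @property
    def size(self) -> int:
        """Number of symbols, |Sigma|."""
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, ch: str) -> bool:
        return ch in self._rank

    def __repr__(self) -> str:
        return f"Alphabet({''.join(self.symbols)!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alphabet) and other.symbols == self.symbols

    def __hash__(self) -> int:
        return hash(self.symbols)

    def index(self, ch: str) -> int:
        """Rank of a symbol (0-based position in the alphabet order)."""
        try:
            return self._rank[ch]
        except KeyError:
            raise ValueError(f"character {ch!r} not in alphabet") from None

    def encode(self, text: str) -> np.ndarray:
        """Encode a string as a ``uint8`` array of symbol ranks.

        Raises ``ValueError`` naming the first offending position if a
        character is outside the alphabet.
        """
        raw = np.frombuffer(text.encode("ascii", errors="replace"), dtype=np.uint8)
        codes = self._lut[raw]
        bad = np.nonzero(codes == 255)[0]
        if bad.size:
            pos = int(bad[0])
            raise ValueError(
                f"character {text[pos]!r} at position {pos} is not in the alphabet"
            )
        return codes

    def decode(self, codes: np.ndarray) -> str:
        """Inverse of :meth:`encode` for a 1-D rank array."""
        return self._bytes[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")

    def decode_rows(self, codes: np.ndarray) -> list[str]:
        """Decode each row of a 2-D rank array to a string."""
        mat = self._bytes[np.asarray(codes, dtype=np.uint8)]
        width = mat.shape[1] if mat.ndim == 2 else 0
        flat = mat.tobytes().decode("ascii")
        return [flat[i : i + width] for i in range(0, len(flat), width)] if width else []


#: Strict four-letter DNA alphabet (no ambiguity codes).
DNA = Alphabet("ACGT")

#: The 20 standard amino acids in alphabetical order.
PROTEIN = Alphabet("ACDEFGHIKLMNPQRSTVWY")
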