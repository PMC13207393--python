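"""Validated nucleotide sequences over the DNA or RNA alphabet.

A :class:`NucSeq` is an immutable string of bases plus a declared alphabet.
All cipher layers operate on the canonical 2-bit value view (A=0, C=1, G=2,
T/U=3); under this ordering the Watson-Crick complement is simply ``3 - v``
for both alphabets.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import AlphabetError


class Alphabet(enum.Enum):
    DNA = "ACGT"
    RNA = "ACGU"

    @property
    def letters(self) -> str:
        return self.value


# base character -> canonical 2-bit value (A=0, C=1, G=2, T/U=3)
_VALUE_TABLES = {
    alph: np.full(256, 255, dtype=np.uint8) for alph in Alphabet
}
for _alph in Alphabet:
    for _i, _b in enumerate(_alph.letters):
        _VALUE_TABLES[_alph][ord(_b)] = _i

_CHAR_TABLES = {
    alph: np.frombuffer(alph.letters.encode(), dtype=np.uint8)
    for alph in Alphabet
}

_COMPLEMENT_TRANS = {
    Alphabet.DNA: str.maketrans("ACGT", "TGCA"),
    Alphabet.RNA: str.maketrans("ACGU", "UGCA"),
}


@dataclass(frozen=True)
class NucSeq:
    """Finite sequence of bases over a declared alphabet."""

    seq: str
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        allowed = set(self.alphabet.letters)
        if not set(self.seq) <= allowed:
            bad = sorted(set(self.seq) - allowed)
            raise AlphabetError(
                f"symbols {bad} not in {self.alphabet.name} alphabet "
                f"{self.alphabet.letters!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __str__(self) -> str:
        return self.seq

    def __iter__(self):
        return iter(self.seq)

    def values(self) -> np.ndarray:
        """Canonical 2-bit values (A=0, C=1, G=2, T/U=3) as uint8."""
        raw = np.frombuffer(self.seq.encode(), dtype=np.uint8)
        return _VALUE_TABLES[self.alphabet][raw]

    @classmethod
    def from_values(cls, values: np.ndarray, alphabet: Alphabet) -> "NucSeq":
        values = np.asarray(values, dtype=np.uint8)
        if values.size and values.max() > 3:
            raise AlphabetError("2-bit values must lie in 0..3")
        chars = _CHAR_TABLES[alphabet][values]
        return cls(chars.tobytes().decode("ascii"), alphabet)

    def complemented(self) -> "NucSeq":
        """Positionwise Watson-Crick complement (same alphabet)."""
        return NucSeq(self.seq.translate(_COMPLEMENT_TRANS[self.alphabet]),
                      self.alphabet)


def as_nucseq(seq: "NucSeq | str", alphabet: Alphabet) -> NucSeq:
    """Coerce a plain string to a NucSeq; verify alphabet if already one."""
    if isinstance(seq, NucSeq):
        if seq.alphabet is not alphabet:
            raise AlphabetError(
                f"expected {alphabet.name} sequence, got {seq.alphabet.name}"
            )
        return seq
    return NucSeq(seq, alphabet)
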