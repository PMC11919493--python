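"""Analytic combinatorics of semantide sequence spaces.

A *semantide* is an informational biopolymer (DNA, RNA, protein) whose
sequence carries lineage information.  Its naive polymorphic space -- the
set of all sequences of length ``L`` over ``k`` monomers -- has ``k**L``
members, a number that overflows every native numeric type for realistic
genes (``4**120 ~ 1.8e72``).  All sizes and probabilities are therefore
handled exclusively in log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

DNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SemantideSpec:
    """A gene/polymer description: length ``L`` over an alphabet of ``k`` monomers.

    ``length == 0`` is accepted as a degenerate identity case (the empty
    sequence), anchoring algebraic property tests.
    """

    length: int
    alphabet_size: int = 4
    alphabet: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"length must be >= 0, got {self.length}")
        if self.alphabet_size < 2:
            raise ValueError(f"alphabet_size must be >= 2, got {self.alphabet_size}")
        if self.alphabet is None:
            if self.alphabet_size == 4:
                object.__setattr__(self, "alphabet", DNA_ALPHABET)
            else:
                object.__setattr__(
                    self,
                    "alphabet",
                    tuple(f"m{i}" for i in range(self.alphabet_size)),
                )
        else:
            object.__setattr__(self, "alphabet", tuple(self.alphabet))
        if len(self.alphabet) != self.alphabet_size:
            raise ValueError(
                f"alphabet has {len(self.alphabet)} symbols, expected {self.alphabet_size}"
            )
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet symbols must be unique")

    @classmethod
    def dna(cls, length: int) -> "SemantideSpec":
        return cls(length=length, alphabet_size=4, alphabet=DNA_ALPHABET)

    @classmethod
    def protein(cls, length: int, alphabet_size: int = 21) -> "SemantideSpec":
        """Protein semantide; 21 or 22 proteinogenic amino acids, caller's choice."""
        if alphabet_size not in (21, 22):
            raise ValueError("protein alphabets have 21 or 22 monomers")
        return cls(length=length, alphabet_size=alphabet_size)


def blind_permutation_log_probability(spec: SemantideSpec) -> float:
    """log10 probability of drawing one given sequence by blind permutation.

    P(L, k) = (1/k)**L, returned as ``-L * log10(k)`` -- exact in log space,
    never underflows.
    """
    return -spec.length * math.log10(spec.alphabet_size)


def space_log_size(spec: SemantideSpec) -> float:
    """log10 of the naive polymorphic space size ``k**L``.

    Exactly the negation of :func:`blind_permutation_log_probability`.
    """
    return spec.length * math.log10(spec.alphabet_size)
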