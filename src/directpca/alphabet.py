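"""Residue alphabets for one-hot encoding of alignments.

An :class:`Alphabet` fixes the ordered set of residue symbols that spans the
indicator (one-hot) coordinates of the sequence matrix.  For nucleotide and
protein data the gap character ``-`` is a first-class symbol placed last, so
that indels contribute to differences between samples exactly like
substitutions do.  Ambiguity codes (IUPAC nucleotide codes, ``X``/``B``/``Z``
for proteins) are not symbols of their own: they are encoded as the uniform
distribution over their compatible non-gap symbols, which preserves the
per-position unit mass while contributing no directional signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Tuple

__all__ = ["Alphabet", "DNA", "PROTEIN", "BINARY", "get_alphabet"]

_IUPAC_DNA: Mapping[str, str] = MappingProxyType(
    {
        "R": "AG",
        "Y": "CT",
        "S": "GC",
        "W": "AT",
        "K": "GT",
        "M": "AC",
        "B": "CGT",
        "D": "AGT",
        "H": "ACT",
        "V": "ACG",
        "N": "ACGT",
    }
)

_PROTEIN_AMBIGUITY: Mapping[str, str] = MappingProxyType(
    {
        "B": "DN",
        "Z": "EQ",
        "J": "IL",
        "X": "ACDEFGHIKLMNPQRSTVWY",
    }
)


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet of size ``k``, optionally including a gap.

    Parameters
    ----------
    name:
        Short identifier used in reports ("dna", "protein", "binary").
    symbols:
        Ordered residue characters.  When a gap is present it must be the
        final symbol.
    gap:
        The gap character, or ``None`` for gap-free alphabets (used by the
        two-symbol simulation alphabet).
    ambiguity:
        Mapping from ambiguity code to the string of compatible non-gap
        symbols it stands for.
    """

    name: str
    symbols: Tuple[str, ...]
    gap: str | None = "-"
    ambiguity: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError(f"alphabet symbols must be unique: {self.symbols}")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least two symbols")
        if self.gap is not None:
            if self.symbols.count(self.gap) != 1 or self.symbols[-1] != self.gap:
                raise ValueError("gap must appear exactly once, as the final symbol")
        for code, compat in self.ambiguity.items():
            if code in self.symbols:
                raise ValueError(f"ambiguity code {code!r} clashes with a symbol")
            if not compat or any(c not in self.symbols for c in compat):
                raise ValueError(f"ambiguity code {code!r} maps outside the alphabet")

    @property
    def k(self) -> int:
        """Alphabet size (number of indicator coordinates per position)."""
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)


#: DNA alphabet A, T, G, C, gap (k = 5), in the column order of the encoded matrix.
DNA = Alphabet("dna", ("A", "T", "G", "C", "-"), gap="-", ambiguity=_IUPAC_DNA)

#: The 20 standard amino acids plus gap (k = 21).
PROTEIN = Alphabet(
    "protein",
    tuple("ACDEFGHIKLMNPQRSTVWY") + ("-",),
    gap="-",
    ambiguity=_PROTEIN_AMBIGUITY,
)

#: Gap-free two-symbol alphabet for the +1/-1 divergence simulations (k = 2).
BINARY = Alphabet("binary", ("A", "T"), gap=None)

_REGISTRY = {a.name: a for a in (DNA, PROTEIN, BINARY)}


def get_alphabet(name: str) -> Alphabet:
    """Look up a built-in alphabet by name ("dna", "protein" or "binary")."""
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown alphabet {name!r}; choose from {sorted(_REGISTRY)}"
        ) from None
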