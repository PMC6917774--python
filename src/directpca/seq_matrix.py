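"""Aligned sequences and their one-hot (boolean) sequence matrix.

The sequence matrix X is the numerical form of a multiple alignment: each
aligned position of each sample becomes a block of ``k`` indicator
coordinates, one per alphabet symbol (gap included), and the blocks are laid
out letter-major — all positions of the first symbol, then all positions of
the second, and so on — so a row is the concatenation of ``k`` boolean
vectors of length ``l``.  The two-sample alignment {TAGC, GAGC} becomes::

         A     T     G     C     -
    ( 0100  1000  0010  0001  0000 )
    ( 0100  0000  1010  0001  0000 )

The encoding is lossless: for unambiguous residues it is inverted exactly by
:func:`decode_one_hot`.  Ambiguity codes are spread uniformly over their
compatible symbols (keeping each position block summing to one) and cannot be
decoded back to a single character.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import DNA, Alphabet

__all__ = [
    "AlignmentError",
    "AlignedSequences",
    "SequenceMatrix",
    "read_alignment",
    "write_alignment",
    "encode_one_hot",
    "decode_one_hot",
    "consensus_sequence",
]


class AlignmentError(ValueError):
    """Malformed alignment input (ragged lengths, duplicate ids, bad symbols)."""


def _normalize(seq: str, alphabet: Alphabet) -> str:
    s = seq.upper().replace(".", "-").replace("~", "-")
    if alphabet.name == "dna":
        s = s.replace("U", "T")
    return s


@dataclass
class AlignedSequences:
    """A multiple alignment: ``n`` rows of identical length ``l``.

    ``rows`` holds normalized character strings (upper case, ``U``→``T`` for
    DNA, ``.``/``~``→``-``); ``ids`` are unique and keep input order.
    """

    ids: list[str]
    rows: list[str]
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if not self.rows:
            raise AlignmentError("alignment is empty")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        self.rows = [_normalize(r, self.alphabet) for r in self.rows]
        l = len(self.rows[0])
        if l < 1:
            raise AlignmentError(f"record {self.ids[0]!r} is empty")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != l:
                raise AlignmentError(
                    f"record {sid!r} has length {len(row)}, expected {l}: "
                    "sequences must be pre-aligned to a common length"
                )

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def l(self) -> int:  # noqa: E743 - l is the field's standard name
        return len(self.rows[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignedSequences):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.rows == other.rows
            and self.alphabet == other.alphabet
        )


@dataclass
class SequenceMatrix:
    """One-hot encoded alignment: ``n`` × ``(k·l)`` matrix in [0, 1].

    Column ``s·l + j`` is the indicator of symbol ``s`` (alphabet order) at
    alignment position ``j`` (0-based internally; positions are reported
    1-based in every output).  Each per-position block of ``k`` entries sums
    to exactly one; entries are 0/1 except where an ambiguity code spread its
    unit mass.
    """

    values: np.ndarray
    ids: list[str]
    l: int  # noqa: E741
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.alphabet.k
        if self.values.shape != (len(self.ids), k * self.l):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"n={len(self.ids)}, k*l={k * self.l}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def blocks(self) -> np.ndarray:
        """View of the matrix as (n, k, l): symbol-by-position blocks."""
        return self.values.reshape(self.n, self.alphabet.k, self.l)


def read_alignment(path, format: str = "fasta", alphabet: Alphabet = DNA) -> AlignedSequences:
    """Read a pre-aligned FASTA file into an :class:`AlignedSequences`.

    Record order and ids are preserved; sequences are normalized (upper case,
    ``U``→``T`` for DNA, ``.``/``~``→``-``).  Raises :class:`AlignmentError`
    for an empty file, duplicate ids, or unequal record lengths.
    """
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise AlignmentError(f"no sequence records found in {path}")
    return AlignedSequences(
        ids=[r.id for r in records],
        rows=[str(r.seq) for r in records],
        alphabet=alphabet,
    )


def write_alignment(aligned: AlignedSequences, path) -> None:
    """Write an alignment as FASTA; round-trips with :func:`read_alignment`."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aligned.ids, aligned.rows)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def encode_one_hot(aligned: AlignedSequences) -> SequenceMatrix:
    """Encode an alignment as the letter-major one-hot sequence matrix.

    Unambiguous residues become unit indicators; ambiguity codes become the
    uniform distribution over their compatible symbols.  A character outside
    the alphabet and the ambiguity table raises :class:`AlignmentError`
    naming the sample, 1-based position and character.
    """
    ab = aligned.alphabet
    n, l, k = aligned.n, aligned.l, ab.k
    chars = np.array([list(r) for r in aligned.rows])  # (n, l)
    blocks = np.zeros((n, k, l))
    for s_idx, sym in enumerate(ab.symbols):
        blocks[:, s_idx, :] = chars == sym
    unresolved = ~np.isin(chars, list(ab.symbols))
    if unresolved.any():
        for code, compat in ab.ambiguity.items():
            hit = chars == code
            if not hit.any():
                continue
            weight = 1.0 / len(compat)
            for c in compat:
                blocks[:, ab.index(c), :] += weight * hit
            unresolved &= ~hit
    if unresolved.any():
        i, j = np.argwhere(unresolved)[0]
        raise AlignmentError(
            f"sample {aligned.ids[i]!r} position {j + 1}: character "
            f"{chars[i, j]!r} is not in the {ab.name} alphabet"
        )
    return SequenceMatrix(blocks.reshape(n, k * l), list(aligned.ids), l, ab)


def decode_one_hot(X: SequenceMatrix) -> AlignedSequences:
    """Decode an unambiguous sequence matrix back to characters.

    Exact inverse of :func:`encode_one_hot` for 0/1 matrices.  A position
    block without exactly one unit entry (e.g. from an ambiguity code) cannot
    name a single residue and raises :class:`AlignmentError`.
    """
    blocks = X.blocks()
    is_unit = blocks == 1.0
    bad = (is_unit.sum(axis=1) != 1) | ((blocks != 0) & ~is_unit).any(axis=1)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise AlignmentError(
            f"sample {X.ids[i]!r} position {j + 1}: block "
            f"{blocks[i, :, j]} is not a unit indicator and cannot be decoded"
        )
    symbol_idx = np.argmax(is_unit, axis=1)  # (n, l)
    symbols = np.array(X.alphabet.symbols)
    rows = ["".join(symbols[r]) for r in symbol_idx]
    return AlignedSequences(list(X.ids), rows, X.alphabet)


def consensus_sequence(X: SequenceMatrix) -> str:
    """Majority-rule consensus: per position, the symbol of highest mean.

    Ties break toward the earlier symbol in alphabet order, making the
    consensus deterministic.
    """
    means = X.blocks().mean(axis=0)  # (k, l)
    symbols = np.array(X.alphabet.symbols)
    return "".join(symbols[np.argmax(means, axis=0)])
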