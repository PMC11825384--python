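"""Sequence validation and base-readout encodings/distances.

A base pair presents an ordered pattern of chemical groups to a protein in
each groove: hydrogen-bond acceptors and donors, nonpolar hydrogens, and the
thymine methyl group.  Reading the groove edges in a fixed spatial order
(5'->3' along the reference strand across the pair) gives four groups on the
major-groove edge and three on the minor-groove edge.  Encoding each group
as a length-4 one-hot yields a 16-slot major vector and a 12-slot minor
vector per base pair (28 slots total, exactly 7 of them set).

Three base-readout distances are provided:

* :func:`physchem_distance` -- L1 difference of the 28-slot functional-group
  vectors, summed over positions.  Distinguishes substitution types
  (transversions to the complementary base flip every major-groove group;
  a C->A change shares more edge chemistry).
* :func:`onehot_distance` -- L1 over plain base one-hots; 2x Hamming.
* :func:`levenshtein_distance` -- unit-cost edit distance; the only base
  metric defined for unequal lengths.

The functional-group code is an injective map on bases, so it carries the
same information as one-hot encoding; the induced *metrics* differ because
different substitutions change different numbers of groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Tuple

import numpy as np

from .errors import AlphabetError, EmptySequenceError, LengthMismatchError

ALPHABET: Tuple[str, ...] = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_RC_TABLE = str.maketrans("ACGT", "TGCA")


class NucleotideSequence(str):
    """A validated DNA sequence over {A, C, G, T}.

    Subclasses :class:`str`: slicing, iteration and comparison behave like a
    plain string, but construction normalizes case and rejects anything
    outside the four canonical bases (including IUPAC ambiguity codes).
    User-facing coordinates are 1-based; this class itself indexes 0-based
    like any Python string.
    """

    def __new__(cls, bases: str) -> "NucleotideSequence":
        if isinstance(bases, NucleotideSequence):
            return bases
        s = str(bases).strip().upper()
        if not s:
            raise EmptySequenceError("empty sequence: need at least one base")
        bad = set(s) - set(ALPHABET)
        if bad:
            raise AlphabetError(
                f"invalid symbol(s) {sorted(bad)}: only A, C, G, T are supported"
            )
        return super().__new__(cls, s)

    @property
    def n(self) -> int:
        """Number of base pairs."""
        return len(self)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.translate(_RC_TABLE)[::-1])

    def codes(self) -> np.ndarray:
        """Base indices (A=0, C=1, G=2, T=3) as an int64 array."""
        return np.array([_BASE_INDEX[b] for b in self], dtype=np.int64)


def reverse_complement(s: "str | NucleotideSequence") -> NucleotideSequence:
    """Watson-Crick reverse complement."""
    return NucleotideSequence(s).reverse_complement()


class FunctionalGroup(Enum):
    """Chemical group a base pair presents at a groove edge position."""

    ACCEPTOR = 0
    DONOR = 1
    NONPOLAR_H = 2
    METHYL = 3

    def one_hot(self) -> np.ndarray:
        v = np.zeros(4, dtype=np.int8)
        v[self.value] = 1
        return v


_A = FunctionalGroup.ACCEPTOR
_D = FunctionalGroup.DONOR
_H = FunctionalGroup.NONPOLAR_H
_M = FunctionalGroup.METHYL

# Groove-edge group patterns, read 5'->3' along the reference strand across
# the pair.  A:T from the A side; G:C from the G side.  The complementary
# base reads the same physical edge from the other strand, i.e. the reversed
# list.  Minor-groove patterns are palindromic, so A/T and G/C share them:
# the minor-groove edge cannot resolve base-pair orientation.
_MAJOR_GROUPS = {
    "A": (_A, _D, _A, _M),
    "G": (_A, _A, _D, _H),
}
_MAJOR_GROUPS["T"] = tuple(reversed(_MAJOR_GROUPS["A"]))
_MAJOR_GROUPS["C"] = tuple(reversed(_MAJOR_GROUPS["G"]))

_MINOR_GROUPS = {
    "A": (_A, _H, _A),
    "G": (_A, _D, _A),
}
_MINOR_GROUPS["T"] = tuple(reversed(_MINOR_GROUPS["A"]))
_MINOR_GROUPS["C"] = tuple(reversed(_MINOR_GROUPS["G"]))


@dataclass(frozen=True)
class BasePairEncoding:
    """Functional-group encoding of one base pair.

    ``major_vector`` concatenates the four major-groove group one-hots
    (16 slots); ``minor_vector`` the three minor-groove one-hots (12 slots).
    """

    base: str
    major_groups: Tuple[FunctionalGroup, ...]
    minor_groups: Tuple[FunctionalGroup, ...]

    @property
    def major_vector(self) -> np.ndarray:
        return np.concatenate([g.one_hot() for g in self.major_groups])

    @property
    def minor_vector(self) -> np.ndarray:
        return np.concatenate([g.one_hot() for g in self.minor_groups])

    @property
    def vector(self) -> np.ndarray:
        """The full 28-slot concatenation (major then minor)."""
        return np.concatenate([self.major_vector, self.minor_vector])


def encode_base_pair(base: str) -> BasePairEncoding:
    """Encode one base pair by its groove-edge functional groups.

    Raises :class:`AlphabetError` for anything outside {A, C, G, T}.
    """
    b = str(base).upper()
    if b not in _BASE_INDEX:
        raise AlphabetError(f"invalid symbol {base!r}: only A, C, G, T are supported")
    return BasePairEncoding(
        base=b, major_groups=_MAJOR_GROUPS[b], minor_groups=_MINOR_GROUPS[b]
    )


# Per-base 28-slot vectors and the induced 4x4 single-position L1 cost table,
# precomputed once from the frozen group patterns above.
_VECTORS = np.stack([encode_base_pair(b).vector for b in ALPHABET])
_PAIR_COST = np.abs(_VECTORS[:, None, :] - _VECTORS[None, :, :]).sum(axis=2)


def _as_pair(s1, s2) -> Tuple[NucleotideSequence, NucleotideSequence]:
    a, b = NucleotideSequence(s1), NucleotideSequence(s2)
    if len(a) != len(b):
        raise LengthMismatchError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "base distances other than Levenshtein require equal lengths"
        )
    return a, b


def physchem_distance(s1, s2) -> int:
    """Functional-group base-readout distance.

    Sum over positions of the L1 difference between the 28-slot
    functional-group vectors of the two base pairs.  Per substitution the
    cost is 6 (A<->C, G<->T), 8 (transitions and A<->T, C<->G), reflecting
    how many groove-edge groups the substitution actually changes.
    """
    a, b = _as_pair(s1, s2)
    return int(
        sum(_PAIR_COST[_BASE_INDEX[x], _BASE_INDEX[y]] for x, y in zip(a, b))
    )


def onehot_distance(s1, s2) -> int:
    """L1 distance between position-wise base one-hots: 2x Hamming distance."""
    a, b = _as_pair(s1, s2)
    return 2 * sum(x != y for x, y in zip(a, b))


def levenshtein_distance(s1, s2) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion).

    Standard two-row dynamic program; lengths may differ.
    """
    a, b = NucleotideSequence(s1), NucleotideSequence(s2)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, y in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (x != y),  # substitution / match
            )
        prev = cur
    return prev[-1]
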