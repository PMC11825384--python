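"""Exception hierarchy.

Every error a user can trigger derives from :class:`ShapemutError`, so the
CLI can catch one type and print a single actionable message.
"""


class ShapemutError(Exception):
    """Base class for all shapemut errors."""


class AlphabetError(ShapemutError):
    """Sequence contains a symbol outside {A, C, G, T}."""


class EmptySequenceError(ShapemutError):
    """A sequence of length zero was supplied."""


class LengthMismatchError(ShapemutError):
    """Two sequences (or profiles) that must be equal-length are not."""


class UnknownFeatureError(ShapemutError):
    """A shape-feature name not present in the catalogue."""


class InvalidWindowError(ShapemutError):
    """k-mer window width is not an odd integer in the supported range."""


class TableFormatError(ShapemutError):
    """A k-mer table file is malformed (duplicate/ragged/non-numeric/mixed k)."""


class MissingKmerError(ShapemutError):
    """A k-mer table does not cover all 4^k k-mers for a claimed feature."""


class ParityError(ShapemutError):
    """A table violates reverse-complement parity (only when checks are strict)."""


class PositionLimitError(ShapemutError):
    """More mutable positions requested than the combinatorial budget allows."""


class CoordinateError(ShapemutError):
    """A 1-based position falls outside the sequence, or is duplicated."""


class EmptyFocalError(ShapemutError):
    """Focal restriction left no indices to compare."""


class InsufficientFocalError(ShapemutError):
    """Too few focal values for a correlation-based distance (need >= 3)."""


class DegenerateCorrelationError(ShapemutError):
    """Pearson distance requested on a zero-variance restricted profile."""


class AmbiguousInputError(ShapemutError):
    """A FASTA input held zero or more than one record."""
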