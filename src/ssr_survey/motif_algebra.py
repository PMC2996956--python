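"""Canonical algebra of short tandem-repeat motifs.

A microsatellite motif is identified up to cyclic rotation of its repeat
unit: an ``(AG)n`` tract read in a different phase looks like ``(GA)n`` but
is the same locus.  This module provides the rotation-equivalence classes
of primitive repeat units (units that are not themselves a whole-number
repetition of a shorter unit), a stable canonical representative for each
class, and GC-content utilities used when pooling motifs by base
composition.

Canonicalization is by cyclic rotation only — reverse complements are kept
distinct, so ``AG`` and ``CT`` are different classes.  This yields 6
dinucleotide and 20 trinucleotide classes, which are the class counts
(df + 1) used by the goodness-of-fit tests downstream.  The canonical
representative is the lexicographically smallest rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

__all__ = [
    "MotifClass",
    "MotifError",
    "AlphabetError",
    "PrimitivityError",
    "MotifLengthError",
    "canonical_motif",
    "enumerate_motif_classes",
    "is_primitive",
    "rotations",
    "gc_fraction",
]

NUCLEOTIDES = "ACGT"

MIN_UNIT_LENGTH = 2
MAX_UNIT_LENGTH = 6


class MotifError(ValueError):
    """Base class for invalid repeat-unit inputs."""


class AlphabetError(MotifError):
    """Unit contains characters outside the A/C/G/T alphabet."""


class PrimitivityError(MotifError):
    """Unit is a whole-number repetition of a shorter unit (e.g. ``ATAT``)."""


class MotifLengthError(MotifError):
    """Unit length outside the supported 2–6 bp range."""


def _validate_alphabet(unit: str) -> str:
    unit = unit.upper()
    if not unit:
        raise AlphabetError("empty repeat unit")
    if any(base not in NUCLEOTIDES for base in unit):
        raise AlphabetError(f"repeat unit {unit!r} contains non-ACGT characters")
    return unit


def is_primitive(unit: str) -> bool:
    """True iff *unit* is not a whole-number repetition of a shorter string.

    ``AT`` is primitive; ``ATAT`` (period 2) and ``AAA`` (period 1) are not.
    Only proper divisors of the length can produce an exact repetition.
    """
    unit = _validate_alphabet(unit)
    n = len(unit)
    for period in range(1, n):
        if n % period == 0 and unit[:period] * (n // period) == unit:
            return False
    return True


def rotations(unit: str) -> tuple[str, ...]:
    """All cyclic rotations of *unit*, starting with the unit itself."""
    unit = _validate_alphabet(unit)
    return tuple(unit[i:] + unit[:i] for i in range(len(unit)))


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest cyclic rotation of a primitive repeat unit.

    Idempotent, and identical for every rotation of the same unit, so it
    serves as a stable class label ("GA" -> "AG", "TAT" -> "ATT").

    Raises
    ------
    AlphabetError
        On characters outside A/C/G/T.
    MotifLengthError
        If the unit length is outside 2–6 bp.
    PrimitivityError
        If the unit is a repetition of a shorter unit.
    """
    unit = _validate_alphabet(unit)
    if not MIN_UNIT_LENGTH <= len(unit) <= MAX_UNIT_LENGTH:
        raise MotifLengthError(
            f"repeat unit {unit!r} has length {len(unit)}; expected "
            f"{MIN_UNIT_LENGTH}-{MAX_UNIT_LENGTH} bp"
        )
    if not is_primitive(unit):
        raise PrimitivityError(f"repeat unit {unit!r} is not primitive")
    return min(rotations(unit))


def gc_fraction(unit: str) -> float:
    """Fraction of G or C bases in *unit*, in [0, 1]."""
    unit = _validate_alphabet(unit)
    return (unit.count("G") + unit.count("C")) / len(unit)


@dataclass(frozen=True)
class MotifClass:
    """A rotation-equivalence class of primitive repeat units.

    Attributes
    ----------
    canonical : str
        Lexicographically smallest rotation; the class label.
    members : frozenset[str]
        All rotations of the canonical unit.  For a primitive unit of
        length L there are exactly L distinct rotations.
    unit_length : int
        Repeat unit length in bp.
    gc_fraction : float
        (#G + #C) / unit_length; rotation-invariant.
    """

    canonical: str
    members: frozenset[str] = field(repr=False)
    unit_length: int
    gc_fraction: float

    @classmethod
    def from_unit(cls, unit: str) -> "MotifClass":
        canon = canonical_motif(unit)
        return cls(
            canonical=canon,
            members=frozenset(rotations(canon)),
            unit_length=len(canon),
            gc_fraction=gc_fraction(canon),
        )


def enumerate_motif_classes(unit_length: int) -> list[MotifClass]:
    """All rotation classes of primitive units of a given length, sorted.

    For length 2 there are 6 classes (AC, AG, AT, CG, CT, GT); for length 3
    there are 20 — the class counts behind the df = 5 and df = 19
    goodness-of-fit tests.

    Raises
    ------
    MotifLengthError
        If *unit_length* is outside 2–6.
    """
    if not MIN_UNIT_LENGTH <= unit_length <= MAX_UNIT_LENGTH:
        raise MotifLengthError(
            f"unit_length {unit_length} outside {MIN_UNIT_LENGTH}-{MAX_UNIT_LENGTH}"
        )
    seen: dict[str, MotifClass] = {}
    for combo in product(NUCLEOTIDES, repeat=unit_length):
        unit = "".join(combo)
        if not is_primitive(unit):
            continue
        canon = min(rotations(unit))
        if canon not in seen:
            seen[canon] = MotifClass.from_unit(canon)
    return [seen[c] for c in sorted(seen)]
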