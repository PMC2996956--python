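"""Detection of maximal perfect microsatellite runs.

Only simple, perfect repeats are reported: a locus is a maximal tract that
is an exact tandem repetition of a primitive unit of 2–6 bp, with at least
``min_units`` complete units.  Compound structures (abutting runs of
different motifs) can be filtered afterwards, and runs too close to a read
end can be flagged as unusable for primer design.

The scan works per unit length k by comparing the sequence with itself
shifted k bases: a maximal stretch of positions where ``s[i] == s[i+k]``
(both non-N) of length m corresponds to a perfect period-k tract of length
m + k.  Because a tract of >= min_units >= 2 units with a primitive leading
unit cannot simultaneously carry a shorter period (Fine-Wilf), requiring
primitivity of the unit guarantees the reported unit length is the smallest
period of the run, and the same tract is never reported twice at a multiple
of its period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .library_io import SequenceRead
from .motif_algebra import canonical_motif, is_primitive

__all__ = [
    "SSRLocus",
    "CoordinateError",
    "find_ssrs",
    "find_ssrs_in_library",
    "flag_terminal",
    "filter_compound",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}


class CoordinateError(ValueError):
    """Locus coordinates fall outside the read."""


@dataclass(frozen=True)
class SSRLocus:
    """One detected perfect repeat run.

    Coordinates are 0-based half-open on the forward strand of the read.
    ``repeat_count`` counts complete units only; when partial extension is
    enabled the span may additionally cover a perfect partial trailing
    unit, so ``span_bp`` can exceed ``repeat_count * unit_length`` by up to
    ``unit_length - 1`` bases.
    """

    read_id: str
    start: int
    end: int
    unit_length: int
    observed_unit: str
    motif_class: str
    repeat_count: int
    is_terminal: bool = False
    library_label: str = ""
    orf_placement: str | None = None

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def locus_id(self) -> str:
        return f"{self.read_id}:{self.start}-{self.end}:{self.motif_class}"


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to int8 codes (A=0, C=1, G=2, T=3, N=-1)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    table = np.full(128, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        table[ord(base)] = code
    return table[arr]


def _match_runs(eq: np.ndarray) -> Iterable[tuple[int, int]]:
    """Yield (first, last) index pairs of maximal True runs in a bool array."""
    if not eq.any():
        return
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    yield from zip(starts.tolist(), ends.tolist())


def find_ssrs(
    read: SequenceRead,
    min_units: int = 5,
    unit_lengths: Sequence[int] = range(2, 7),
    partial_extension: bool = True,
) -> list[SSRLocus]:
    """Find all maximal perfect SSR runs in one read.

    Parameters
    ----------
    read : SequenceRead
        Input read; N bases terminate any repeat extension.
    min_units : int
        Minimum number of complete repeat units (default 5).
    unit_lengths : sequence of int
        Unit lengths to scan, each in 2..6.
    partial_extension : bool
        If True (default) the reported span includes a perfect partial
        trailing unit; ``repeat_count`` always counts complete units.

    Returns
    -------
    list of SSRLocus, sorted by (start, unit_length).  Each run is maximal:
    it cannot be perfectly extended in either direction with the same unit.
    """
    if min_units < 2:
        raise ValueError("min_units must be >= 2")
    if any(k < 2 or k > 6 for k in unit_lengths):
        raise ValueError("unit_lengths must lie in 2..6")

    seq = read.sequence
    loci: list[SSRLocus] = []
    if len(seq) < 2 * min(unit_lengths, default=2):
        return loci
    arr = encode(seq)

    for k in sorted(set(unit_lengths)):
        if len(arr) <= k:
            continue
        eq = (arr[:-k] == arr[k:]) & (arr[:-k] >= 0)
        for first, last in _match_runs(eq):
            span = last - first + 1 + k  # tract [first, last + 1 + k)
            count = span // k
            if count < min_units:
                continue
            unit = seq[first : first + k]
            if not is_primitive(unit):
                # already reported at its smallest period
                continue
            end = first + span if partial_extension else first + count * k
            loci.append(
                SSRLocus(
                    read_id=read.read_id,
                    start=first,
                    end=end,
                    unit_length=k,
                    observed_unit=unit,
                    motif_class=canonical_motif(unit),
                    repeat_count=count,
                    library_label=read.library_label,
                )
            )
    loci.sort(key=lambda l: (l.start, l.unit_length))
    return loci


def find_ssrs_in_library(
    lib, min_units: int = 5, unit_lengths: Sequence[int] = range(2, 7),
    partial_extension: bool = True,
) -> list[SSRLocus]:
    """Run :func:`find_ssrs` over every read of a library collection."""
    out: list[SSRLocus] = []
    for read in lib:
        out.extend(find_ssrs(read, min_units, unit_lengths, partial_extension))
    return out


def flag_terminal(
    locus: SSRLocus, read: SequenceRead, min_flank_bp: int
) -> SSRLocus:
    """Return the locus with ``is_terminal`` set.

    A locus is terminal when either flank is shorter than ``min_flank_bp``
    — too close to a read end for primer design.

    Raises
    ------
    CoordinateError
        If the locus does not lie within the read bounds.
    """
    if locus.start < 0 or locus.end > read.length_bp or locus.start >= locus.end:
        raise CoordinateError(
            f"locus [{locus.start}, {locus.end}) outside read "
            f"{read.read_id!r} of length {read.length_bp}"
        )
    terminal = locus.start < min_flank_bp or (read.length_bp - locus.end) < min_flank_bp
    return replace(locus, is_terminal=terminal)


def filter_compound(loci: Sequence[SSRLocus], max_gap_bp: int = 0) -> list[SSRLocus]:
    """Drop compound repeats: loci within ``max_gap_bp`` of another locus.

    The gap between two loci is the number of bases separating their spans
    (negative when they overlap).  Both members of a compound pair are
    removed; the result does not depend on input order.
    """
    loci = sorted(loci, key=lambda l: (l.read_id, l.start, l.end, l.motif_class))
    drop = [False] * len(loci)
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            if a.read_id != b.read_id:
                break
            gap = b.start - a.end
            if gap > max_gap_bp:
                break
            drop[i] = drop[j] = True
    return [loc for loc, d in zip(loci, drop) if not d]
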