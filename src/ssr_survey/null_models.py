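"""Composition-based null models for motif identity and ORF placement.

The expected motif mix of a library is estimated from its own sequence:
every overlapping k-mer on the forward strand is counted, non-primitive
k-mers and k-mers containing N are skipped, counts are pooled by cyclic
rotation class and normalized.  The expected fraction of repeat bases
falling inside open reading frames is likewise taken from the fraction of
library bases covered by the union of ORF spans (optionally restricted to
reads that contain at least one SSR).  A uniform null over motif classes
is provided as the naive alternative.  Observed locus counts are then
tested against either null with the chi-square goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .library_io import LibraryCollection
from .motif_algebra import MotifLengthError, enumerate_motif_classes
from .orf_scan import Orf, OrfPlacement
from .repeat_finder import SSRLocus, encode
from .survey_stats import ChiSquareResult, chi_square_gof

__all__ = [
    "MotifDistribution",
    "OrfBackground",
    "DegenerateBackgroundError",
    "InsufficientCountsError",
    "composition_distribution",
    "uniform_distribution",
    "motif_gof",
    "orf_background",
    "orf_gof",
]


class DegenerateBackgroundError(ValueError):
    """No countable k-mers in the library."""


class InsufficientCountsError(ValueError):
    """Too few loci for a meaningful GOF on rare motif lengths."""


@dataclass(frozen=True)
class MotifDistribution:
    """Null distribution over the canonical motif classes of one unit length."""

    unit_length: int
    class_probs: dict[str, float]
    source: str  # "uniform" | "composition"
    n_kmers_counted: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class OrfBackground:
    """Fraction of library bases covered by the union of ORF spans."""

    fraction_in_orf: float
    bases_in_orf: int
    bases_total: int
    restricted_to_ssr_reads: bool


def _class_lookup(unit_length: int) -> tuple[np.ndarray, list[str]]:
    """Map each k-mer integer code to a class index (-1 for non-primitive)."""
    classes = enumerate_motif_classes(unit_length)
    names = [c.canonical for c in classes]
    index = {name: i for i, name in enumerate(names)}
    table = np.full(4 ** unit_length, -1, dtype=np.int32)
    code_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    for ci, cls in enumerate(classes):
        for member in cls.members:
            code = 0
            for base in member:
                code = code * 4 + code_of[base]
            table[code] = index[cls.canonical]
    return table, names


def composition_distribution(
    lib: LibraryCollection,
    unit_length: int,
    exclude_ssr_spans: bool = False,
    loci: Sequence[SSRLocus] | None = None,
) -> MotifDistribution:
    """Empirical motif-class distribution from library k-mer content.

    Counts every overlapping k-mer of ``unit_length`` on the forward strand
    of every read (k-mers never span reads); k-mers containing N or that
    are non-primitive are skipped; counts are pooled by rotation class.
    When ``exclude_ssr_spans`` is set, positions inside the supplied SSR
    loci are masked out before counting.

    Raises
    ------
    DegenerateBackgroundError
        When no countable k-mer remains.
    """
    if not 2 <= unit_length <= 6:
        raise MotifLengthError(f"unit_length {unit_length} outside 2-6")
    if exclude_ssr_spans and loci is None:
        raise ValueError("exclude_ssr_spans requires the loci to mask")
    table, names = _class_lookup(unit_length)
    counts = np.zeros(len(names), dtype=np.int64)
    spans_by_read: dict[str, list[tuple[int, int]]] = {}
    if exclude_ssr_spans and loci:
        for loc in loci:
            spans_by_read.setdefault(loc.read_id, []).append((loc.start, loc.end))
    k = unit_length
    total = 0
    for read in lib:
        arr = encode(read.sequence).astype(np.int64)
        if arr.size < k:
            continue
        if exclude_ssr_spans:
            for s, e in spans_by_read.get(read.read_id, []):
                arr[s:e] = -1
        codes = np.zeros(arr.size - k + 1, dtype=np.int64)
        valid = np.ones(arr.size - k + 1, dtype=bool)
        for offset in range(k):
            window = arr[offset : arr.size - k + 1 + offset]
            codes = codes * 4 + np.where(window >= 0, window, 0)
            valid &= window >= 0
        cls = table[codes]
        keep = valid & (cls >= 0)
        if keep.any():
            counts += np.bincount(cls[keep], minlength=len(names))
            total += int(keep.sum())
    if total == 0:
        raise DegenerateBackgroundError(
            f"no countable {k}-mers in library (all N or non-primitive)"
        )
    probs = {name: counts[i] / total for i, name in enumerate(names)}
    return MotifDistribution(k, probs, "composition", total)


def uniform_distribution(unit_length: int) -> MotifDistribution:
    """Uniform null: equal probability for every motif class of this length."""
    classes = enumerate_motif_classes(unit_length)
    p = 1.0 / len(classes)
    return MotifDistribution(
        unit_length, {c.canonical: p for c in classes}, "uniform", 0
    )


def motif_gof(
    loci: Sequence[SSRLocus],
    null: MotifDistribution,
    min_loci: int = 20,
) -> ChiSquareResult:
    """Chi-square GOF of observed motif-class locus counts against a null.

    Observed counts are per-class numbers of loci (not repeat bases);
    expected counts are ``class_probs * total``.  df = #classes − 1 (5 for
    dinucleotides, 19 for trinucleotides).  For unit lengths >= 4 the test
    refuses to run below ``min_loci`` total loci, mirroring the exclusion
    of motif lengths too rare for adequate power.
    """
    names = sorted(null.class_probs)
    wrong = [l for l in loci if l.unit_length != null.unit_length]
    if wrong:
        raise ValueError(
            f"{len(wrong)} loci have unit_length != {null.unit_length}"
        )
    obs = np.zeros(len(names), dtype=float)
    index = {name: i for i, name in enumerate(names)}
    for loc in loci:
        obs[index[loc.motif_class]] += 1
    total = obs.sum()
    if total == 0:
        raise ValueError("no loci to test")
    if null.unit_length >= 4 and total < min_loci:
        raise InsufficientCountsError(
            f"{int(total)} loci of unit length {null.unit_length} "
            f"(< {min_loci}): too few for a motif GOF"
        )
    exp = np.array([null.class_probs[name] * total for name in names])
    return chi_square_gof(obs, exp)


def orf_background(
    lib: LibraryCollection,
    orfs: Sequence[Orf],
    loci: Sequence[SSRLocus],
    restrict: bool = True,
) -> OrfBackground:
    """Fraction of selected-read bases covered by the union of ORF spans.

    With ``restrict=True`` (default) only reads containing at least one
    SSR contribute, matching a null built from the sequence actually
    carrying the tested loci.  Overlapping ORF spans are merged before
    measuring coverage.
    """
    ssr_reads = {l.read_id for l in loci}
    selected = [
        r for r in lib if (not restrict) or (r.read_id in ssr_reads)
    ]
    chosen_ids = {r.read_id for r in selected}
    bases_total = sum(r.length_bp for r in selected)
    spans: dict[str, list[tuple[int, int]]] = {}
    for orf in orfs:
        if orf.read_id in chosen_ids:
            spans.setdefault(orf.read_id, []).append((orf.start, orf.end))
    covered = 0
    for intervals in spans.values():
        intervals.sort()
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    frac = covered / bases_total if bases_total else 0.0
    return OrfBackground(frac, covered, bases_total, restrict)


def orf_gof(
    placements: Sequence[OrfPlacement], background: OrfBackground
) -> ChiSquareResult:
    """Chi-square GOF of inside/outside SSR counts against the ORF fraction.

    Expected counts are ``(f·n, (1−f)·n)`` where f is the background ORF
    base fraction.  Bridging placements must already have been removed.
    """
    cats = [p.category for p in placements]
    if any(c == "bridging" for c in cats):
        raise ValueError("bridging placements must be removed before orf_gof")
    n = len(cats)
    if n == 0:
        raise ValueError("no placements to test")
    inside = sum(1 for c in cats if c == "inside")
    outside = n - inside
    f = background.fraction_in_orf
    return chi_square_gof([inside, outside], [f * n, (1 - f) * n])
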