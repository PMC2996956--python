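"""Six-frame open reading frame scanning and SSR placement classification.

An ORF is defined as an ATG start codon through the first in-frame stop
(TAA/TAG/TGA) downstream, stop codon included; every qualifying ATG yields
a candidate, and candidates shorter than ``min_orf_nt`` are discarded.
Reverse-strand ORFs are reported in forward coordinates.

Each SSR is then classified relative to the ORF annotation of its read:
``inside`` when its span is contained in a single ORF, ``outside`` when it
is disjoint from the union of all ORF spans, and ``bridging`` otherwise.
Bridging loci are excluded from the downstream goodness-of-fit tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .library_io import SequenceRead
from .repeat_finder import SSRLocus

__all__ = [
    "Orf",
    "OrfPlacement",
    "PlacementError",
    "find_orfs",
    "find_orfs_in_library",
    "classify_placement",
    "classify_library_placements",
    "write_orfs_gff3",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PlacementError(ValueError):
    """SSR locus and ORF list disagree on read identity."""


@dataclass(frozen=True)
class Orf:
    """An open reading frame in forward-strand 0-based half-open coordinates.

    ``frame`` is the start offset modulo 3 on the ORF's own strand.
    """

    read_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int  # 0..2
    length_nt: int


@dataclass(frozen=True)
class OrfPlacement:
    """Classification of one SSR locus relative to the read's ORFs."""

    locus_id: str
    category: str  # "inside" | "outside" | "bridging"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _scan_strand(seq: str, min_orf_nt: int) -> list[tuple[int, int, int]]:
    """(start, end, frame) of all ATG->stop ORFs on one strand, local coords."""
    n = len(seq)
    out = []
    for frame in range(3):
        # stop-codon positions in this frame, in order
        stops = [p for p in range(frame, n - 2, 3) if seq[p : p + 3] in STOP_CODONS]
        stop_idx = 0
        for p in range(frame, n - 2, 3):
            if seq[p : p + 3] != START_CODON:
                continue
            # first stop at or after p (ATGs visited in ascending order)
            while stop_idx < len(stops) and stops[stop_idx] < p:
                stop_idx += 1
            if stop_idx == len(stops):
                break  # no complete stop downstream in this frame
            end = stops[stop_idx] + 3
            if end - p >= min_orf_nt:
                out.append((p, end, frame))
    return out


def find_orfs(
    read: SequenceRead,
    min_orf_nt: int = 300,
    strands: Sequence[str] = ("+", "-"),
) -> list[Orf]:
    """Find ORFs in all reading frames of the requested strands.

    Parameters
    ----------
    min_orf_nt : int
        Minimum ORF length in nucleotides, stop codon included; must be a
        multiple of 3.  Default 300 nt (100 codons).
    strands : sequence of "+"/"-"
        Strands to scan; reverse-strand ORFs are converted to forward
        coordinates.

    Returns a list sorted by (start, end, strand).
    """
    if min_orf_nt % 3 != 0:
        raise ValueError("min_orf_nt must be a multiple of 3")
    bad = set(strands) - {"+", "-"}
    if bad:
        raise ValueError(f"unknown strand symbols: {sorted(bad)}")
    n = read.length_bp
    orfs: list[Orf] = []
    if "+" in strands:
        for s, e, frame in _scan_strand(read.sequence, min_orf_nt):
            orfs.append(Orf(read.read_id, s, e, "+", frame, e - s))
    if "-" in strands:
        rc = revcomp(read.sequence)
        for s, e, frame in _scan_strand(rc, min_orf_nt):
            orfs.append(Orf(read.read_id, n - e, n - s, "-", frame, e - s))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def find_orfs_in_library(
    lib, min_orf_nt: int = 300, strands: Sequence[str] = ("+", "-")
) -> list[Orf]:
    out: list[Orf] = []
    for read in lib:
        out.extend(find_orfs(read, min_orf_nt, strands))
    return out


def classify_placement(locus: SSRLocus, orfs: Iterable[Orf]) -> OrfPlacement:
    """Classify one SSR as inside / outside / bridging relative to ORFs.

    inside: the SSR span is contained in at least one single ORF.
    outside: the SSR span is disjoint from every ORF.
    bridging: overlaps ORF sequence but is contained in no single ORF
    (straddles an in-frame to out-of-frame boundary).

    Order and duplication of the ORF list are irrelevant.

    Raises
    ------
    PlacementError
        If any ORF belongs to a different read.
    """
    overlaps = False
    for orf in orfs:
        if orf.read_id != locus.read_id:
            raise PlacementError(
                f"ORF read {orf.read_id!r} does not match locus read "
                f"{locus.read_id!r}"
            )
        if orf.start <= locus.start and locus.end <= orf.end:
            return OrfPlacement(locus.locus_id, "inside")
        if locus.start < orf.end and orf.start < locus.end:
            overlaps = True
    return OrfPlacement(locus.locus_id, "bridging" if overlaps else "outside")


def classify_library_placements(
    loci: Sequence[SSRLocus], orfs: Sequence[Orf]
) -> list[OrfPlacement]:
    """Classify every locus against the ORFs of its own read."""
    by_read: dict[str, list[Orf]] = {}
    for orf in orfs:
        by_read.setdefault(orf.read_id, []).append(orf)
    return [
        classify_placement(loc, by_read.get(loc.read_id, [])) for loc in loci
    ]


def write_orfs_gff3(orfs: Iterable[Orf], path: str | Path) -> None:
    """Write ORFs as GFF3 ``ORF`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in orfs:
            fh.write(
                "\t".join(
                    [
                        orf.read_id,
                        "ssr-survey",
                        "ORF",
                        str(orf.start + 1),
                        str(orf.end),
                        ".",
                        orf.strand,
                        str(orf.frame),
                        f"length_nt={orf.length_nt}",
                    ]
                )
                + "\n"
            )
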