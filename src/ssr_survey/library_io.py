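"""Sequence-library input/output and exact-duplicate removal.

Reads FASTA libraries into lightweight record collections, removes exact
full-length sequence duplicates (the only redundancy criterion applied —
no similarity clustering), and writes SSR call tables as TSV or GFF3.

Bases other than A/C/G/T are kept in the sequence as ``N`` placeholders;
they never participate in repeat or k-mer matching downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .repeat_finder import SSRLocus

__all__ = [
    "SequenceRead",
    "LibraryCollection",
    "EmptyLibraryError",
    "read_fasta",
    "write_fasta",
    "deduplicate",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_calls_gff3",
]

_VALID = set("ACGT")


class EmptyLibraryError(ValueError):
    """FASTA file contained no sequence records."""


def _sanitize(seq: str) -> str:
    """Uppercase and collapse every non-ACGT symbol to N."""
    seq = seq.upper()
    if set(seq) <= _VALID:
        return seq
    return "".join(b if b in _VALID else "N" for b in seq)


@dataclass(frozen=True)
class SequenceRead:
    """One sequencing read: BAC-end or EST single-pass sequence."""

    read_id: str
    sequence: str
    library_label: str = ""

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class LibraryCollection:
    """An ordered collection of reads from one library."""

    reads: list[SequenceRead] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(r.length_bp for r in self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __len__(self) -> int:
        return len(self.reads)


def read_fasta(path: str | Path, library_label: str = "") -> LibraryCollection:
    """Load a FASTA file into a :class:`LibraryCollection`.

    Sequences are uppercased (non-ACGT symbols become N), record IDs are the
    first whitespace-delimited token of the header, and input order is
    preserved.  Duplicate IDs are disambiguated with a deterministic
    ``.dupK`` suffix and reported as a warning.

    Raises
    ------
    EmptyLibraryError
        If the file holds no records.
    """
    reads: list[SequenceRead] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}.dup{seen[rid]}"
            warnings.warn(
                f"duplicate read ID {rid!r}; renamed to {new_id!r}", stacklevel=2
            )
            rid = new_id
        else:
            seen[rid] = 0
        reads.append(SequenceRead(rid, _sanitize(str(rec.seq)), library_label))
    if not reads:
        raise EmptyLibraryError(f"no FASTA records in {path}")
    return LibraryCollection(reads)


def write_fasta(lib: LibraryCollection | Iterable[SequenceRead], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in lib
    ]
    SeqIO.write(records, str(path), "fasta")


def deduplicate(lib: LibraryCollection) -> tuple[LibraryCollection, int]:
    """Remove exact full-length sequence duplicates, keeping first occurrence.

    Returns the reduced collection and the number of reads removed.
    Idempotent; the retained multiset of sequences does not depend on the
    input order (only which representative ID survives does).
    """
    seen: set[str] = set()
    kept: list[SequenceRead] = []
    removed = 0
    for read in lib.reads:
        if read.sequence in seen:
            removed += 1
        else:
            seen.add(read.sequence)
            kept.append(read)
    return LibraryCollection(kept), removed


# ---------------------------------------------------------------------------
# SSR call tables

_CALL_COLUMNS = [
    "read_id",
    "start",
    "end",
    "unit_length",
    "observed_unit",
    "motif_class",
    "repeat_count",
    "span_bp",
    "is_terminal",
    "library_label",
]


def calls_to_frame(loci: Iterable["SSRLocus"]) -> pd.DataFrame:
    rows = [
        {col: getattr(loc, col) for col in _CALL_COLUMNS}
        | ({"orf_placement": loc.orf_placement} if getattr(loc, "orf_placement", None) else {})
        for loc in loci
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=_CALL_COLUMNS)
    return df


def write_calls_tsv(loci: Iterable["SSRLocus"], path: str | Path) -> None:
    """Write SSR calls as a tab-separated table (0-based half-open coords)."""
    calls_to_frame(loci).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path) -> list["SSRLocus"]:
    from .repeat_finder import SSRLocus

    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            SSRLocus(
                read_id=row.read_id,
                start=int(row.start),
                end=int(row.end),
                unit_length=int(row.unit_length),
                observed_unit=row.observed_unit,
                motif_class=row.motif_class,
                repeat_count=int(row.repeat_count),
                is_terminal=bool(row.is_terminal),
                library_label=getattr(row, "library_label", "") or "",
                orf_placement=getattr(row, "orf_placement", None) or None,
            )
        )
    return loci


def write_calls_gff3(loci: Iterable["SSRLocus"], path: str | Path) -> None:
    """Write SSR calls as GFF3 ``microsatellite`` features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = (
                f"motif_class={loc.motif_class};observed_unit={loc.observed_unit};"
                f"repeat_count={loc.repeat_count};is_terminal={str(loc.is_terminal).lower()}"
            )
            fh.write(
                "\t".join(
                    [
                        loc.read_id,
                        "ssr-survey",
                        "microsatellite",
                        str(loc.start + 1),
                        str(loc.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
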