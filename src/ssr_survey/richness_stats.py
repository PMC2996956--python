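"""Allelic-richness statistics for microsatellite genotype screens.

A genotype screen is a loci × individuals table of gel band labels (band
sizes are categorical, not measured).  Loci that failed to amplify, that
amplified in only one species, or that showed a null allele in any
individual are removed before analysis, so every retained locus is scored
in the same fixed panel of individuals.  Richness is then a simple count
of distinct allele labels per locus, correlated against the repeat number
of the reference library sequence (Spearman) and compared across motif
groups (Kruskal-Wallis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_algebra import MotifError, gc_fraction
from .survey_stats import RankTestResult

__all__ = [
    "MISSING",
    "LocusInfo",
    "GenotypeTable",
    "LocusRichness",
    "CorrelationResult",
    "ScreeningReport",
    "ConsistencyError",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "apply_screening_filters",
    "allelic_richness",
    "spearman_rho",
    "richness_heterogeneity",
    "pool_by_repeat_bins",
    "gc_bin",
    "BAC_REPEAT_BINS",
    "EST_REPEAT_BINS",
]

MISSING = "NA"

#: Reference repeat-number pooling bins (inclusive bounds; None = open-ended).
BAC_REPEAT_BINS: list[tuple[int, int | None]] = [
    (5, 5), (6, 6), (7, 8), (9, 20), (21, 42),
]
EST_REPEAT_BINS: list[tuple[int, int | None]] = [
    (5, 5), (6, 6), (7, 7), (8, 8), (9, None),
]

SCREEN_STATUSES = ("ok", "failed_all", "single_species", "null_allele")


class ConsistencyError(ValueError):
    """Screen log and genotype calls disagree."""


@dataclass(frozen=True)
class LocusInfo:
    locus_id: str
    library_label: str
    motif_class: str
    unit_length: int
    reference_repeat_count: int


@dataclass
class GenotypeTable:
    """Loci × individuals table of allele labels.

    Each cell is either MISSING or a ``/``-joined set of distinct band
    labels for that individual (diploid duplicate bands collapsed).
    """

    loci: list[LocusInfo]
    individuals: list[str]
    calls: list[list[str]]  # row per locus, column per individual

    def __post_init__(self) -> None:
        if any(len(row) != len(self.individuals) for row in self.calls):
            raise ValueError("call matrix does not match individuals")
        if len(self.calls) != len(self.loci):
            raise ValueError("call matrix does not match loci")

    @property
    def n_loci(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class LocusRichness:
    locus_id: str
    richness: int
    reference_repeat_count: int
    motif_class: str
    library_label: str = ""
    gc_bin: int | None = None
    orf_placement: str | None = None


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class ScreeningReport:
    n_screened: int
    n_retained: int
    removed: dict[str, int] = field(default_factory=dict)


def gc_bin(motif_class: str) -> int:
    """Nearest-percent GC category of a trinucleotide motif: 0/33/67/100."""
    if len(motif_class) != 3:
        raise MotifError(f"gc_bin is defined for trinucleotides, got {motif_class!r}")
    return {0: 0, 1: 33, 2: 67, 3: 100}[round(gc_fraction(motif_class) * 3)]


# ---------------------------------------------------------------------------
# TSV dialect: locus_id, library, motif, unit_length, ref_repeat_count, then
# one column per individual ("NA" for missing).

_META_COLS = ["locus_id", "library", "motif", "unit_length", "ref_repeat_count"]


def write_genotypes_tsv(table: GenotypeTable, path: str | Path) -> None:
    rows = []
    for info, row in zip(table.loci, table.calls):
        rec = {
            "locus_id": info.locus_id,
            "library": info.library_label,
            "motif": info.motif_class,
            "unit_length": info.unit_length,
            "ref_repeat_count": info.reference_repeat_count,
        }
        rec.update(dict(zip(table.individuals, row)))
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table lacks columns: {missing}")
    individuals = [c for c in df.columns if c not in _META_COLS]
    loci = [
        LocusInfo(
            locus_id=r["locus_id"],
            library_label=r["library"],
            motif_class=r["motif"],
            unit_length=int(r["unit_length"]),
            reference_repeat_count=int(r["ref_repeat_count"]),
        )
        for _, r in df.iterrows()
    ]
    calls = df[individuals].values.tolist()
    return GenotypeTable(loci, individuals, calls)


def apply_screening_filters(
    table: GenotypeTable, screen_log: Mapping[str, str]
) -> tuple[GenotypeTable, ScreeningReport]:
    """Apply the marker-screen filters and account for every removal.

    ``screen_log`` maps locus_id to one of ``ok``, ``failed_all``,
    ``single_species`` or ``null_allele``.  Only ``ok`` loci are retained;
    an ``ok`` locus with a MISSING call is a consistency error (richness
    must be estimated on the full panel of individuals).
    """
    removed = {s: 0 for s in SCREEN_STATUSES if s != "ok"}
    kept_loci: list[LocusInfo] = []
    kept_calls: list[list[str]] = []
    for info, row in zip(table.loci, table.calls):
        status = screen_log.get(info.locus_id, "ok")
        if status not in SCREEN_STATUSES:
            raise ValueError(f"unknown screen status {status!r} for {info.locus_id}")
        if status == "ok":
            if MISSING in row:
                raise ConsistencyError(
                    f"locus {info.locus_id} marked ok but has missing calls"
                )
            kept_loci.append(info)
            kept_calls.append(row)
        else:
            removed[status] += 1
    report = ScreeningReport(
        n_screened=table.n_loci, n_retained=len(kept_loci), removed=removed
    )
    return GenotypeTable(kept_loci, table.individuals, kept_calls), report


def _bands(cell: str) -> set[str]:
    return set() if cell == MISSING else set(cell.split("/"))


def allelic_richness(table: GenotypeTable) -> list[LocusRichness]:
    """Count distinct allele labels per locus across all individuals jointly."""
    out: list[LocusRichness] = []
    for info, row in zip(table.loci, table.calls):
        labels: set[str] = set()
        for cell in row:
            labels |= _bands(cell)
        out.append(
            LocusRichness(
                locus_id=info.locus_id,
                richness=len(labels),
                reference_repeat_count=info.reference_repeat_count,
                motif_class=info.motif_class,
                library_label=info.library_label,
                gc_bin=gc_bin(info.motif_class) if info.unit_length == 3 else None,
            )
        )
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-corrected Spearman correlation (Pearson on mid-ranks).

    Two-sided p-value from the t approximation.  Zero variance in either
    vector gives a NaN sentinel rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(math.nan, math.nan, int(x.size))
    res = stats.spearmanr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def richness_heterogeneity(
    groups: Mapping[str, Sequence[float]]
) -> RankTestResult:
    """Kruskal-Wallis test of richness across motif/GC/placement groups.

    Empty groups are dropped (noted); fewer than two nonempty groups is an
    input error.  H is tie-corrected; p comes from the chi-square(k−1)
    approximation.
    """
    nonempty = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v)}
    if len(nonempty) < len(groups):
        import warnings

        warnings.warn(
            f"dropped {len(groups) - len(nonempty)} empty group(s)", stacklevel=2
        )
    if len(nonempty) < 2:
        raise ValueError("need at least two nonempty groups")
    pooled = np.concatenate(list(nonempty.values()))
    if np.unique(pooled).size == 1:
        # every observation tied: no heterogeneity, H is identically 0
        return RankTestResult(
            statistic=0.0,
            p=1.0,
            n_per_group=tuple(int(v.size) for v in nonempty.values()),
            tie_correction_applied=True,
            method="kruskal-wallis",
        )
    res = stats.kruskal(*nonempty.values())
    return RankTestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        n_per_group=tuple(int(v.size) for v in nonempty.values()),
        tie_correction_applied=True,
        method="kruskal-wallis",
    )


def pool_by_repeat_bins(
    loci: Sequence[LocusRichness],
    bins: Sequence[tuple[int, int | None]],
) -> pd.DataFrame:
    """Cross-tabulate repeat-number bin × allelic richness.

    ``bins`` are disjoint (lo, hi) inclusive intervals; ``hi = None`` means
    open-ended.  Every locus must fall in exactly one bin.  Rows are bins
    (labelled "lo-hi" or "lo+" or "lo"), columns are richness values, cells
    are locus counts; marginals are preserved (Σ cells == n loci).
    """
    def label(lo: int, hi: int | None) -> str:
        if hi is None:
            return f"{lo}+"
        return str(lo) if lo == hi else f"{lo}-{hi}"

    labels = [label(lo, hi) for lo, hi in bins]
    richness_values = sorted({l.richness for l in loci})
    counts = pd.DataFrame(
        0, index=labels, columns=richness_values, dtype=int
    )
    for loc in loci:
        n = loc.reference_repeat_count
        hits = [
            i for i, (lo, hi) in enumerate(bins)
            if lo <= n and (hi is None or n <= hi)
        ]
        if len(hits) != 1:
            raise ValueError(
                f"repeat count {n} of {loc.locus_id} falls in {len(hits)} bins"
            )
        counts.loc[labels[hits[0]], loc.richness] += 1
    return counts
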