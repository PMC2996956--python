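"""Per-library SSR density summaries and cross-library comparisons.

Summaries report how often repeats occur (reads per SSR, kb per SSR, the
percentage of sequenced bases inside repeats) and how long their repeat
structures are.  Two libraries are compared with a chi-square test of SSR
counts against exposure-proportional expectations, and with a Mann-Whitney
U test on per-locus repeat counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .library_io import LibraryCollection
from .repeat_finder import SSRLocus

__all__ = [
    "SurveySummary",
    "ChiSquareResult",
    "RankTestResult",
    "summarize_library",
    "compare_abundance",
    "compare_repeat_counts",
    "chi_square_gof",
]


@dataclass(frozen=True)
class ChiSquareResult:
    """Chi-square goodness-of-fit result: X² = Σ (O−E)²/E, p from χ²(df)."""

    statistic: float
    df: int
    p: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney U or Kruskal-Wallis H result with tie handling noted."""

    statistic: float
    p: float
    n_per_group: tuple[int, ...]
    tie_correction_applied: bool = True
    method: str = ""


@dataclass(frozen=True)
class SurveySummary:
    """Density and length summary for one library (undefined fields are NaN)."""

    library_label: str
    n_reads: int
    total_bases: int
    n_ssr: int
    reads_per_ssr: float
    kb_per_ssr: float
    pct_ssr_bases: float
    mean_repeat_count: float
    n_terminal: int
    n_designable: int


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float]
) -> ChiSquareResult:
    """Chi-square GOF of observed counts against expected counts.

    ``df`` is ``len(observed) - 1``.  Cells with expected < 5 are noted as
    warnings; a cell with expected 0 but observed > 0 yields an infinite
    statistic (p = 0) with an error note rather than an exception.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1 or obs.size < 2:
        raise ValueError("observed and expected must be equal-length vectors (>= 2)")
    warn: list[str] = []
    if (exp < 5).any():
        warn.append(f"{int((exp < 5).sum())} cell(s) with expected count < 5")
    df = obs.size - 1
    if ((exp == 0) & (obs > 0)).any():
        warn.append("observed counts in zero-expectation cell: statistic is infinite")
        return ChiSquareResult(
            math.inf, df, 0.0, tuple(obs), tuple(exp), tuple(warn)
        )
    mask = exp > 0
    stat = float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())
    p = float(stats.chi2.sf(stat, df))
    return ChiSquareResult(stat, df, p, tuple(obs), tuple(exp), tuple(warn))


def summarize_library(
    lib: LibraryCollection,
    loci: Sequence[SSRLocus],
    n_unprimeable: int = 0,
) -> SurveySummary:
    """Summarize SSR density and repeat length for one library.

    With zero loci the per-SSR densities and the mean repeat count are
    reported as NaN sentinels rather than raising a division error.
    ``n_designable`` subtracts terminal loci and any externally supplied
    count of loci lacking suitable priming sites.
    """
    n_ssr = len(loci)
    total_bases = lib.total_bases
    n_terminal = sum(1 for l in loci if l.is_terminal)
    if n_ssr == 0:
        reads_per = kb_per = mean_units = math.nan
        pct = 0.0
    else:
        reads_per = lib.n_reads / n_ssr
        kb_per = total_bases / 1000.0 / n_ssr
        pct = 100.0 * sum(l.span_bp for l in loci) / total_bases
        mean_units = float(np.mean([l.repeat_count for l in loci]))
    label = lib.reads[0].library_label if lib.n_reads else ""
    return SurveySummary(
        library_label=label,
        n_reads=lib.n_reads,
        total_bases=total_bases,
        n_ssr=n_ssr,
        reads_per_ssr=reads_per,
        kb_per_ssr=kb_per,
        pct_ssr_bases=pct,
        mean_repeat_count=mean_units,
        n_terminal=n_terminal,
        n_designable=max(n_ssr - n_terminal - n_unprimeable, 0),
    )


def compare_abundance(
    a: SurveySummary,
    b: SurveySummary,
    exposure: str = "bases",
    continuity: bool = False,
) -> ChiSquareResult:
    """Chi-square test of SSR counts in two libraries against exposure.

    Observed counts are (n_ssr_a, n_ssr_b); expected counts split the total
    proportionally to the chosen exposure (``"reads"`` or ``"bases"``).
    df = 1.  The optional Yates continuity correction is off by default.
    """
    if exposure == "reads":
        ea, eb = a.n_reads, b.n_reads
    elif exposure == "bases":
        ea, eb = a.total_bases, b.total_bases
    else:
        raise ValueError("exposure must be 'reads' or 'bases'")
    if ea <= 0 or eb <= 0:
        raise ValueError("both libraries must have nonzero exposure")
    total = a.n_ssr + b.n_ssr
    exp_a = total * ea / (ea + eb)
    exp_b = total * eb / (ea + eb)
    obs = np.array([a.n_ssr, b.n_ssr], dtype=float)
    exp = np.array([exp_a, exp_b], dtype=float)
    warn: list[str] = []
    if (exp < 5).any():
        warn.append("expected cell < 5")
    if continuity:
        stat = float((((np.abs(obs - exp) - 0.5).clip(min=0)) ** 2 / exp).sum())
    else:
        stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, 1))
    return ChiSquareResult(stat, 1, p, tuple(obs), tuple(exp), tuple(warn))


def _as_counts(values: Sequence) -> np.ndarray:
    arr = [v.repeat_count if isinstance(v, SSRLocus) else v for v in values]
    return np.asarray(arr, dtype=float)


def compare_repeat_counts(
    loci_a: Sequence, loci_b: Sequence
) -> RankTestResult:
    """Two-sided Mann-Whitney U test on per-locus repeat counts.

    Accepts SSRLocus lists or plain numeric sequences.  Uses the exact null
    distribution when ``n1 * n2 <= 400`` and there are no ties, otherwise
    the tie-corrected normal approximation.
    """
    x, y = _as_counts(loci_a), _as_counts(loci_b)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size * y.size <= 400) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return RankTestResult(
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        n_per_group=(int(x.size), int(y.size)),
        tie_correction_applied=not exact,
        method="exact" if exact else "normal-approx",
    )
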