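"""Synthetic sequence libraries and genotype screens with known ground truth.

The generator emulates the two library types the survey pipeline consumes:
single-pass sequencing reads (~700 bp) of i.i.d. background bases with
perfect SSR tracts of known motif class and unit count planted at known
coordinates, optional planted ORFs, and genotype screens in which the
per-locus allele-pool size grows log-linearly with the reference repeat
number.  Every feature is recorded in a truth set so detector recovery,
false-positive rates, and statistical power are all measurable.

Planted tracts get flank rejection: the bases immediately adjacent to a
tract are redrawn so they cannot extend the repeat, making coordinate-exact
recovery a fair test.  All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .library_io import LibraryCollection, SequenceRead
from .motif_algebra import enumerate_motif_classes
from .orf_scan import STOP_CODONS
from .richness_stats import (
    MISSING,
    GenotypeTable,
    LocusInfo,
)
from .repeat_finder import SSRLocus

__all__ = [
    "SimulationConfig",
    "PlantedSSR",
    "PlantedOrf",
    "TruthSet",
    "ConfigError",
    "default_motif_weights",
    "generate_library",
    "generate_genotypes",
]

_BASES = "ACGT"


class ConfigError(ValueError):
    """Simulation parameters are infeasible or inconsistent."""


def default_motif_weights() -> dict[str, float]:
    """Default planted-motif mix: AT-skewed dinucleotides dominate.

    Roughly 72.5% dinucleotide, 25% trinucleotide and 2.5% tetranucleotide
    loci, with dinucleotides biased toward AT-rich classes — the mix seen
    in insect genomic libraries where motif lengths above 3 are rare.
    """
    weights: dict[str, float] = {}
    di = {"AT": 0.40, "AC": 0.20, "AG": 0.20, "CT": 0.10, "GT": 0.08, "CG": 0.02}
    for motif, w in di.items():
        weights[motif] = 0.725 * w
    tri = enumerate_motif_classes(3)
    for cls in tri:
        weights[cls.canonical] = 0.25 / len(tri)
    tetra = enumerate_motif_classes(4)
    for cls in tetra:
        weights[cls.canonical] = 0.025 / len(tetra)
    return weights


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; the defaults are the survey conditions.

    Reads average 703 bp (the mean single-pass read length of the surveyed
    libraries); background bases are i.i.d. with mild AT richness
    (GC = 0.35, typical of insect genomic sequence); one planted SSR per
    read on average; unit counts are 5 + Poisson(3) complete units (mean 8,
    spanning the 5–20+ range the screens cover).  The genotype model draws
    the per-locus allele-pool size as 1 + Poisson(exp(a + b·n)) with n the
    reference repeat number, so b > 0 yields richness rising with repeat
    number and b = 0 is the null.
    """

    seed: int = 0
    n_reads: int = 500
    read_length_mean: float = 703.0
    read_length_sd: float = 120.0
    min_read_length: int = 100
    base_probs: tuple[float, float, float, float] = (0.325, 0.175, 0.175, 0.325)
    ssr_per_read_rate: float = 1.0
    motif_class_weights: dict[str, float] = field(default_factory=default_motif_weights)
    unit_count_min: int = 5
    unit_count_poisson_mean: float = 3.0
    orf_density_per_kb: float = 0.0
    orf_length_codons: int = 110
    # genotype model
    richness_intercept: float = -1.0
    richness_slope: float = 0.25
    allele_step_geometric_q: float = 0.5
    failed_all_rate: float = 0.0
    single_species_rate: float = 0.0
    null_allele_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ConfigError("base_probs must sum to 1")
        if any(p < 0 for p in self.base_probs):
            raise ConfigError("base_probs must be nonnegative")
        if self.unit_count_min < 2:
            raise ConfigError("unit_count_min must be >= 2")
        total_w = sum(self.motif_class_weights.values())
        if total_w <= 0:
            raise ConfigError("motif_class_weights must have positive mass")


@dataclass(frozen=True)
class PlantedSSR:
    read_id: str
    start: int
    end: int
    motif_class: str
    observed_unit: str
    unit_count: int


@dataclass(frozen=True)
class PlantedOrf:
    read_id: str
    start: int
    end: int


@dataclass
class TruthSet:
    ssrs: list[PlantedSSR] = field(default_factory=list)
    orfs: list[PlantedOrf] = field(default_factory=list)
    allele_pool_sizes: dict[str, int] = field(default_factory=dict)


def _random_bases(rng: np.random.Generator, n: int, probs) -> list[str]:
    return [_BASES[i] for i in rng.choice(4, size=n, p=probs)]


def _non_extending_base(
    rng: np.random.Generator, forbidden: str, probs
) -> str:
    while True:
        b = _BASES[int(rng.choice(4, p=probs))]
        if b != forbidden:
            return b


def _orf_construct(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons − 2) random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        codon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
        if codon not in STOP_CODONS and codon != "ATG":
            codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def generate_library(
    config: SimulationConfig, library_label: str = "SIM"
) -> tuple[LibraryCollection, TruthSet]:
    """Generate a read library with planted SSR tracts (and optional ORFs).

    Background bases are i.i.d. from ``base_probs``.  Each read receives a
    Poisson(``ssr_per_read_rate``) number of tracts at uniform positions,
    rejecting overlaps; the bases flanking each tract are redrawn so they
    cannot perfectly extend the repeat, and planted tracts keep at least
    one background base to each read end.  Deterministic given the seed.

    Raises
    ------
    ConfigError
        If a read would need more than half its bases inside planted SSRs.
    """
    rng = np.random.default_rng(config.seed)
    probs = np.asarray(config.base_probs, dtype=float)
    motifs = sorted(config.motif_class_weights)
    weights = np.array([config.motif_class_weights[m] for m in motifs], dtype=float)
    weights = weights / weights.sum()

    reads: list[SequenceRead] = []
    truth = TruthSet()
    for ridx in range(config.n_reads):
        read_id = f"{library_label}_{ridx:06d}"
        length = max(
            config.min_read_length,
            int(round(rng.normal(config.read_length_mean, config.read_length_sd))),
        )
        seq = _random_bases(rng, length, probs)

        n_ssr = int(rng.poisson(config.ssr_per_read_rate))
        planted: list[tuple[int, int, str, int]] = []  # start, end, unit, count
        tract_total = 0
        for _ in range(n_ssr):
            motif = motifs[int(rng.choice(len(motifs), p=weights))]
            count = config.unit_count_min + int(
                rng.poisson(config.unit_count_poisson_mean)
            )
            k = len(motif)
            phase = int(rng.integers(0, k))
            unit = motif[phase:] + motif[:phase]
            span = count * k
            if tract_total + span > length // 2:
                raise ConfigError(
                    f"planted SSR bases would exceed half of read {read_id} "
                    f"({length} bp)"
                )
            placed = False
            for _attempt in range(200):
                start = int(rng.integers(2, length - span - 2 + 1))
                end = start + span
                # keep >= 2 bp clearance between tracts for flank fixing
                if all(end + 2 <= s or e + 2 <= start for s, e, *_ in planted):
                    placed = True
                    break
            if not placed:
                continue  # crowded read: drop this tract
            tract = unit * count
            seq[start:end] = list(tract)
            # flank rejection: adjacent bases must not extend the repeat
            seq[start - 1] = _non_extending_base(rng, tract[k - 1], probs)
            if end < length:
                seq[end] = _non_extending_base(rng, tract[span - k], probs)
            else:  # pragma: no cover - placement keeps 2 bp right margin
                pass
            planted.append((start, end, unit, count))
            tract_total += span

        if config.orf_density_per_kb > 0:
            occupied = [(s, e) for s, e, *_ in planted]
            n_orf = int(rng.poisson(config.orf_density_per_kb * length / 1000.0))
            for _ in range(n_orf):
                construct = _orf_construct(rng, config.orf_length_codons)
                m = len(construct)
                if m + 4 > length:
                    continue
                for _attempt in range(100):
                    start = int(rng.integers(2, length - m - 2 + 1))
                    end = start + m
                    if all(end <= s - 2 or e + 2 <= start for s, e in occupied):
                        seq[start:end] = list(construct)
                        truth.orfs.append(PlantedOrf(read_id, start, end))
                        occupied.append((start, end))
                        break

        sequence = "".join(seq)
        reads.append(SequenceRead(read_id, sequence, library_label))
        for start, end, unit, count in sorted(planted):
            canon = min(unit[i:] + unit[:i] for i in range(len(unit)))
            truth.ssrs.append(
                PlantedSSR(read_id, start, end, canon, unit, count)
            )
    return LibraryCollection(reads), truth


def generate_genotypes(
    loci: Sequence[SSRLocus],
    config: SimulationConfig,
    n_individuals: int = 8,
) -> tuple[GenotypeTable, TruthSet, dict[str, str]]:
    """Simulate a genotype screen over detected (or planted) SSR loci.

    For a locus with reference repeat number n the allele pool holds
    ``k = 1 + Poisson(exp(a + b*n))`` distinct length variants (truncated
    at 2 × n_individuals), stepwise around the reference length; each
    individual carries two draws weighted geometrically toward the
    reference allele, collapsed to distinct band labels.  Loci are marked
    ``failed_all`` / ``single_species`` / ``null_allele`` at the configured
    rates, producing the screen log consumed by the filtering step.

    Returns the table, a truth set with the per-locus pool sizes, and the
    screen log.
    """
    if n_individuals < 2:
        raise ConfigError("n_individuals must be >= 2")
    for rate in (
        config.failed_all_rate,
        config.single_species_rate,
        config.null_allele_rate,
    ):
        if not 0 <= rate <= 1:
            raise ConfigError("status-injection rates must lie in [0, 1]")
    rng = np.random.default_rng(config.seed + 1)
    individuals = [f"ind{j + 1}" for j in range(n_individuals)]
    half = n_individuals // 2
    truth = TruthSet()
    screen_log: dict[str, str] = {}
    infos: list[LocusInfo] = []
    calls: list[list[str]] = []
    q = config.allele_step_geometric_q

    for loc in loci:
        n_ref = loc.repeat_count
        lam = float(np.exp(config.richness_intercept + config.richness_slope * n_ref))
        k = 1 + int(rng.poisson(lam))
        k = min(k, 2 * n_individuals)
        truth.allele_pool_sizes[loc.locus_id] = k
        # stepwise pool around the reference repeat number: 0, +1, -1, +2, ...
        offsets = [0]
        step = 1
        while len(offsets) < k:
            offsets.append(step)
            if len(offsets) < k:
                offsets.append(-step)
            step += 1
        pool = [n_ref + o for o in offsets]
        w = np.array([q ** i for i in range(k)], dtype=float)
        w /= w.sum()

        row: list[str] = []
        for _ in range(n_individuals):
            draws = rng.choice(k, size=2, p=w)
            bands = sorted({str(pool[int(d)]) for d in draws})
            row.append("/".join(bands))

        u = rng.random()
        if u < config.failed_all_rate:
            status = "failed_all"
            row = [MISSING] * n_individuals
        elif u < config.failed_all_rate + config.single_species_rate:
            status = "single_species"
            row = row[:half] + [MISSING] * (n_individuals - half)
        elif u < (
            config.failed_all_rate
            + config.single_species_rate
            + config.null_allele_rate
        ):
            status = "null_allele"
            j = int(rng.integers(0, n_individuals))
            row[j] = MISSING
        else:
            status = "ok"
        screen_log[loc.locus_id] = status
        infos.append(
            LocusInfo(
                locus_id=loc.locus_id,
                library_label=loc.library_label,
                motif_class=loc.motif_class,
                unit_length=loc.unit_length,
                reference_repeat_count=n_ref,
            )
        )
        calls.append(row)
    return GenotypeTable(infos, individuals, calls), truth, screen_log
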