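"""Composition-based and uniform nulls, and the chi-square GOF wrappers."""

import math

import pytest

from ssr_survey.library_io import LibraryCollection, SequenceRead
from ssr_survey.motif_algebra import enumerate_motif_classes
from ssr_survey.null_models import (
    DegenerateBackgroundError,
    InsufficientCountsError,
    composition_distribution,
    motif_gof,
    orf_background,
    orf_gof,
    uniform_distribution,
)
from ssr_survey.orf_scan import Orf, OrfPlacement
from ssr_survey.repeat_finder import SSRLocus

from conftest import oracle_is_primitive, random_sequence


def _lib(*seqs):
    return LibraryCollection(
        [SequenceRead(f"r{i}", s) for i, s in enumerate(seqs)]
    )


def oracle_kmer_class_counts(seqs, k):
    """Naive per-position k-mer counter pooled by min-rotation class."""
    counts = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer or not oracle_is_primitive(kmer):
                continue
            canon = min(kmer[j:] + kmer[:j] for j in range(k))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def test_single_motif_library_is_point_mass():
    dist = composition_distribution(_lib("ACACACACAC"), 2)
    assert dist.class_probs["AC"] == pytest.approx(1.0)
    assert all(v == 0 for c, v in dist.class_probs.items() if c != "AC")
    assert dist.n_kmers_counted == 9


@pytest.mark.parametrize("k", [2, 3])
def test_composition_matches_naive_oracle(rng, k):
    seqs = [random_sequence(rng, 150, n_rate=0.03) for _ in range(100)]
    dist = composition_distribution(_lib(*seqs), k)
    oracle = oracle_kmer_class_counts(seqs, k)
    total = sum(oracle.values())
    assert dist.n_kmers_counted == total
    for cls in enumerate_motif_classes(k):
        assert dist.class_probs[cls.canonical] == pytest.approx(
            oracle.get(cls.canonical, 0) / total
        )


def test_composition_invariant_to_read_order(rng):
    seqs = [random_sequence(rng, 200) for _ in range(20)]
    d1 = composition_distribution(_lib(*seqs), 2)
    d2 = composition_distribution(_lib(*seqs[::-1]), 2)
    assert d1.class_probs == d2.class_probs


def test_composition_kmers_do_not_span_reads():
    # "AC"|"AC" as two reads has no "CA" dimer crossing the boundary
    dist = composition_distribution(_lib("AC", "AC"), 2)
    assert dist.class_probs["AC"] == 1.0
    assert dist.n_kmers_counted == 2


def test_composition_excluding_ssr_spans():
    lib = _lib("ATATATATATGCGCGC")
    loci = [SSRLocus("r0", 0, 10, 2, "AT", "AT", 5)]
    dist = composition_distribution(lib, 2, exclude_ssr_spans=True, loci=loci)
    assert dist.class_probs["AT"] == 0.0
    assert dist.class_probs["CG"] == pytest.approx(1.0)


def test_degenerate_background_errors():
    with pytest.raises(DegenerateBackgroundError):
        composition_distribution(_lib("NNNNNNN"), 2)
    with pytest.raises(DegenerateBackgroundError):
        composition_distribution(_lib("AAAAAAAA"), 2)  # only homopolymer dimers


@pytest.mark.parametrize(
    "k, expected_p", [(2, 1 / 6), (3, 0.05)]
)
def test_uniform_distribution(k, expected_p):
    dist = uniform_distribution(k)
    assert all(p == pytest.approx(expected_p) for p in dist.class_probs.values())


@pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
def test_uniform_normalized(k):
    assert sum(uniform_distribution(k).class_probs.values()) == pytest.approx(1.0)


def _loci_from_counts(counts: dict[str, int]):
    out = []
    for motif, n in counts.items():
        for i in range(n):
            out.append(
                SSRLocus(f"r{motif}{i}", 0, 10 * len(motif), len(motif),
                         motif, motif, 10)
            )
    return out


def test_motif_gof_exact_null_is_zero():
    null = uniform_distribution(2)
    loci = _loci_from_counts({c.canonical: 10 for c in enumerate_motif_classes(2)})
    res = motif_gof(loci, null)
    assert res.statistic == 0.0 and res.p == pytest.approx(1.0)


@pytest.mark.parametrize("k, df", [(2, 5), (3, 19)])
def test_motif_gof_degrees_of_freedom(k, df):
    loci = _loci_from_counts(
        {c.canonical: 5 for c in enumerate_motif_classes(k)}
    )
    assert motif_gof(loci, uniform_distribution(k)).df == df


def test_motif_gof_zero_expected_sentinel():
    null = composition_distribution(_lib("ACACACACAC"), 2)  # P(AC) == 1
    loci = _loci_from_counts({"AC": 5, "AT": 1})
    res = motif_gof(loci, null)
    assert math.isinf(res.statistic) and res.p == 0.0


def test_motif_gof_rare_unit_lengths_refuse_small_samples():
    loci = _loci_from_counts({"AAAT": 5})
    with pytest.raises(InsufficientCountsError):
        motif_gof(loci, uniform_distribution(4))
    # explicit lower threshold allows it
    res = motif_gof(loci, uniform_distribution(4), min_loci=5)
    assert res.df == len(enumerate_motif_classes(4)) - 1


def test_motif_gof_unit_length_mismatch():
    loci = _loci_from_counts({"ACG": 5})
    with pytest.raises(ValueError):
        motif_gof(loci, uniform_distribution(2))


def test_uniform_vs_composition_disagree_on_biased_library(rng):
    # library strongly enriched for AT dimers
    seqs = ["AT" * 50 + random_sequence(rng, 100) for _ in range(30)]
    lib = _lib(*seqs)
    loci = _loci_from_counts({"AT": 30, "AC": 10, "AG": 10, "CT": 5, "GT": 5})
    r_uni = motif_gof(loci, uniform_distribution(2))
    r_comp = motif_gof(loci, composition_distribution(lib, 2))
    assert r_uni.statistic != pytest.approx(r_comp.statistic)


def test_orf_background_edges():
    lib = _lib("A" * 100, "C" * 100)
    loci = [SSRLocus("r0", 10, 30, 2, "AT", "AT", 10)]
    bg = orf_background(lib, [], loci, restrict=True)
    assert bg.fraction_in_orf == 0.0 and bg.bases_total == 100
    full = [Orf("r0", 0, 100, "+", 0, 100)]
    bg2 = orf_background(lib, full, loci, restrict=True)
    assert bg2.fraction_in_orf == 1.0


def test_orf_background_union_merges_overlaps():
    lib = _lib("A" * 100)
    loci = [SSRLocus("r0", 0, 10, 2, "AT", "AT", 5)]
    orfs = [
        Orf("r0", 10, 40, "+", 0, 30),
        Orf("r0", 30, 60, "-", 0, 30),
        Orf("r0", 80, 90, "+", 0, 10),
    ]
    bg = orf_background(lib, orfs, loci, restrict=False)
    # union = [10,60) + [80,90) = 60 bases
    assert bg.bases_in_orf == 60
    assert bg.fraction_in_orf == pytest.approx(0.6)


def test_orf_background_restriction_to_ssr_reads():
    lib = _lib("A" * 100, "C" * 200)
    loci = [SSRLocus("r1", 10, 30, 2, "AT", "AT", 10)]  # only read r1
    orfs = [Orf("r0", 0, 100, "+", 0, 100), Orf("r1", 0, 50, "+", 0, 50)]
    bg = orf_background(lib, orfs, loci, restrict=True)
    assert bg.bases_total == 200 and bg.bases_in_orf == 50
    bg_all = orf_background(lib, orfs, loci, restrict=False)
    assert bg_all.bases_total == 300 and bg_all.bases_in_orf == 150


def _placements(inside, outside):
    return (
        [OrfPlacement(f"i{k}", "inside") for k in range(inside)]
        + [OrfPlacement(f"o{k}", "outside") for k in range(outside)]
    )


def test_orf_gof_hand_formula():
    from ssr_survey.null_models import OrfBackground

    bg = OrfBackground(0.5, 50, 100, True)
    res = orf_gof(_placements(8, 2), bg)
    assert res.statistic == pytest.approx(3.6)
    assert res.df == 1


def test_orf_gof_observed_fraction_is_null():
    from ssr_survey.null_models import OrfBackground

    bg = OrfBackground(0.25, 25, 100, True)
    res = orf_gof(_placements(5, 15), bg)
    assert res.statistic == pytest.approx(0.0)


def test_orf_gof_rejects_bridging():
    from ssr_survey.null_models import OrfBackground

    with pytest.raises(ValueError):
        orf_gof(_placements(3, 3) + [OrfPlacement("b", "bridging")],
                OrfBackground(0.5, 1, 2, True))
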