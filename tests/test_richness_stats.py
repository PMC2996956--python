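"""Genotype screening filters, allelic richness, and rank statistics."""

import math

import numpy as np
import pytest
from scipy import stats

from ssr_survey.motif_algebra import MotifError
from ssr_survey.richness_stats import (
    BAC_REPEAT_BINS,
    MISSING,
    ConsistencyError,
    GenotypeTable,
    LocusInfo,
    LocusRichness,
    allelic_richness,
    apply_screening_filters,
    gc_bin,
    pool_by_repeat_bins,
    read_genotypes_tsv,
    richness_heterogeneity,
    spearman_rho,
    write_genotypes_tsv,
)


def _info(i, motif="AT", ref=8):
    return LocusInfo(f"L{i}", "BAC", motif, len(motif), ref)


def _table(rows, individuals=None):
    individuals = individuals or [f"ind{j}" for j in range(len(rows[0]))]
    return GenotypeTable([_info(i) for i in range(len(rows))], individuals, rows)


@pytest.mark.parametrize(
    "motif, expected",
    [("AAT", 0), ("ATT", 0), ("ACT", 33), ("ACG", 67), ("CCG", 100)],
)
def test_gc_bin_categories(motif, expected):
    assert gc_bin(motif) == expected


def test_gc_bin_rejects_non_trinucleotides():
    with pytest.raises(MotifError):
        gc_bin("AT")


def test_screening_toy_table_one_of_each_failure():
    rows = [
        ["1", "1", "1", "1"],
        [MISSING] * 4,
        ["1", "1", MISSING, MISSING],
        ["1", "2", "1", MISSING],
        ["2", "2", "1", "1"],
    ]
    table = _table(rows)
    log = {"L0": "ok", "L1": "failed_all", "L2": "single_species",
           "L3": "null_allele", "L4": "ok"}
    filtered, report = apply_screening_filters(table, log)
    assert filtered.n_loci == 2
    assert report.n_screened == 5 and report.n_retained == 2
    assert report.removed == {"failed_all": 1, "single_species": 1,
                              "null_allele": 1}
    assert report.n_retained + sum(report.removed.values()) == 5


def test_screening_all_ok_is_identity():
    table = _table([["1", "2"], ["3", "3"]])
    filtered, report = apply_screening_filters(table, {})
    assert filtered.calls == table.calls
    assert report.removed == {"failed_all": 0, "single_species": 0,
                              "null_allele": 0}


def test_screening_ok_with_missing_is_inconsistent():
    table = _table([["1", MISSING]])
    with pytest.raises(ConsistencyError):
        apply_screening_filters(table, {"L0": "ok"})


def test_richness_counts_distinct_labels():
    table = _table([["A", "B", "A", "A", "B", "C", "A", "A"],
                    ["x", "x", "x", "x", "x", "x", "x", "x"]])
    rich = allelic_richness(table)
    assert [r.richness for r in rich] == [3, 1]


def test_richness_splits_diploid_band_cells():
    table = _table([["142/146", "142", "146/150", "142"]])
    assert allelic_richness(table)[0].richness == 3


def test_richness_saturates_at_pool_size(rng):
    pool = [str(v) for v in range(4)]
    for n_ind in (2, 8, 32):
        rows = [[pool[int(rng.integers(0, 4))] for _ in range(n_ind)]]
        r = allelic_richness(_table(rows))[0].richness
        assert r <= 4
    big = [[pool[int(rng.integers(0, 4))] for _ in range(500)]]
    assert allelic_richness(_table(big))[0].richness == 4


def test_spearman_perfect_monotone():
    res = spearman_rho([1, 2, 3, 4, 5], [2, 4, 9, 16, 30])
    assert res.rho == pytest.approx(1.0)
    assert res.n == 5


def test_spearman_matches_midrank_pearson_oracle():
    x = [5, 5, 6, 7, 8, 8, 9]
    y = [2, 3, 3, 4, 4, 6, 5]

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    expected = float(np.corrcoef(rx, ry)[0, 1])
    assert spearman_rho(x, y).rho == pytest.approx(expected)


def test_spearman_zero_variance_sentinel():
    res = spearman_rho([3, 3, 3, 3], [1, 2, 3, 4])
    assert math.isnan(res.rho) and math.isnan(res.p)


def test_spearman_permutation_null_calibration(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    rejections = sum(
        spearman_rho(x, rng.permutation(y)).p < 0.05 for _ in range(400)
    )
    assert 0.02 <= rejections / 400 <= 0.08


def test_heterogeneity_identical_groups_h_zero():
    res = richness_heterogeneity({"a": [2, 2, 2], "b": [2, 2, 2]})
    assert res.statistic == pytest.approx(0.0)


def test_heterogeneity_hand_formula_no_ties():
    groups = {"a": [1, 4, 6], "b": [2, 3, 9], "c": [5, 7, 8]}
    # H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1), ranks of 1..9 are themselves
    ranks = {"a": [1, 4, 6], "b": [2, 3, 9], "c": [5, 7, 8]}
    n = 9
    h = 12 / (n * (n + 1)) * sum(
        sum(r) ** 2 / len(r) for r in ranks.values()
    ) - 3 * (n + 1)
    res = richness_heterogeneity(groups)
    assert res.statistic == pytest.approx(h)
    assert res.n_per_group == (3, 3, 3)


def test_heterogeneity_two_groups_equals_squared_normal_mw(rng):
    x = list(rng.normal(size=25))
    y = list(rng.normal(loc=0.7, size=30))
    res = richness_heterogeneity({"x": x, "y": y})
    u = stats.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    z = stats.norm.isf(u.pvalue / 2)
    assert res.statistic == pytest.approx(z ** 2, rel=1e-6)


def test_heterogeneity_input_validation():
    with pytest.raises(ValueError):
        richness_heterogeneity({"only": [1, 2, 3]})
    with pytest.warns(UserWarning, match="empty group"):
        res = richness_heterogeneity({"a": [1, 2], "b": [3, 4], "c": []})
    assert res.n_per_group == (2, 2)


def _rich(i, ref, richness=3):
    return LocusRichness(f"L{i}", richness, ref, "AT", "BAC")


def test_pool_by_repeat_bins_default_bac_bins():
    loci = [_rich(i, ref) for i, ref in enumerate([5, 6, 7, 8, 9, 20, 21, 42])]
    table = pool_by_repeat_bins(loci, BAC_REPEAT_BINS)
    assert list(table.index) == ["5", "6", "7-8", "9-20", "21-42"]
    assert table.values.sum() == len(loci)
    assert table.loc["7-8"].sum() == 2
    assert table.loc["21-42"].sum() == 2


def test_pool_by_repeat_bins_conservation(rng):
    loci = [_rich(i, int(rng.integers(5, 43)), int(rng.integers(1, 12)))
            for i in range(60)]
    table = pool_by_repeat_bins(loci, BAC_REPEAT_BINS)
    assert table.values.sum() == 60


def test_pool_by_repeat_bins_out_of_range_errors():
    with pytest.raises(ValueError):
        pool_by_repeat_bins([_rich(0, 4)], BAC_REPEAT_BINS)


def test_genotype_tsv_round_trip(tmp_path):
    table = _table([["142/146", "142", MISSING, "150"],
                    ["9", "9", "9", "9"]])
    path = tmp_path / "geno.tsv"
    write_genotypes_tsv(table, path)
    back = read_genotypes_tsv(path)
    assert back.individuals == table.individuals
    assert back.calls == table.calls
    assert back.loci == table.loci
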