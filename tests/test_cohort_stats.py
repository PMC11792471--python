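"""Statistics layer: phenotype labels, chi-square, Mann-Whitney AUC,
Spearman, Theil-Sen, prevalence summaries and FMT fold changes."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import baiscan as b

from .oracles import auc_by_pair_counting, chi2_by_formula, spearman_by_rank_formula


def test_phenotype_labels_and_tie_rule():
    assert b.ba_phenotype(3, 1) == b.HIGH_SBA
    assert b.ba_phenotype(0.5, 1) == b.LOW_SBA
    # high-SBA requires strictly more DCA than CA
    assert b.ba_phenotype(1, 1) == b.LOW_SBA
    with pytest.raises(ValueError):
        b.ba_phenotype(1, 0)
    with pytest.raises(ValueError):
        b.ba_phenotype(-1, 1)


def test_chi2_independence_gives_zero():
    res = b.chi2_association([[10, 10], [10, 10]])
    assert res.statistic == 0
    assert res.p_value == 1
    assert res.degrees_of_freedom == 1


def test_chi2_three_by_two_matches_formula_and_dof():
    table = np.array([[30, 70], [16, 84], [4, 96]])
    res = b.chi2_association(table)
    stat, dof = chi2_by_formula(table)
    assert res.statistic == pytest.approx(stat)
    assert res.degrees_of_freedom == dof == 2
    assert res.n == table.sum()


def test_chi2_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        b.chi2_association([[0, 0], [5, 5]])
    with pytest.raises(ValueError):
        b.chi2_association([[1, 2]])


@pytest.mark.parametrize("seed", range(20))
def test_chi2_matches_expected_count_oracle_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(3, 6)), int(rng.integers(2, 5)))
    table = rng.integers(1, 60, size=shape)
    res = b.chi2_association(table)
    stat, dof = chi2_by_formula(table)
    assert res.statistic == pytest.approx(stat)
    assert res.degrees_of_freedom == dof


def test_mwu_auc_examples():
    res = b.mwu_auc([1, 2], [3, 4])
    assert (res.statistic, res.auc) == (4.0, 1.0)
    assert b.mwu_auc([1, 3], [2, 4]).auc == pytest.approx(0.75)
    assert b.mwu_auc([5, 5, 5], [5, 5, 5]).auc == pytest.approx(0.5)
    with pytest.raises(ValueError):
        b.mwu_auc([], [1])


@given(
    st.lists(st.integers(0, 5), min_size=1, max_size=8),
    st.lists(st.integers(0, 5), min_size=1, max_size=8),
)
def test_mwu_auc_equals_pair_counting(g1, g2):
    assert b.mwu_auc(g1, g2).auc == pytest.approx(auc_by_pair_counting(g1, g2))


def test_spearman_examples():
    x = [1.0, 2.5, 3.1, 7.0, 9.2]
    rho, _ = b.spearman(x, x)
    assert rho == pytest.approx(1.0)
    rho, _ = b.spearman(x, [-v for v in x])
    assert rho == pytest.approx(-1.0)
    rho, _ = b.spearman([1, 2, 3, 4], [2, 1, 4, 3])
    assert rho == pytest.approx(spearman_by_rank_formula([1, 2, 3, 4], [2, 1, 4, 3]))
    with pytest.raises(ValueError):
        b.spearman([1, 1, 1], [1, 2, 3])


def test_theil_sen_examples():
    slope, intercept = b.theil_sen([0, 1, 2], [0, 1, 2])
    assert (slope, intercept) == (1.0, 0.0)
    # pairwise slopes {1, 0, -1} -> median 0; residuals {0, 1, 0} -> median 0
    slope, intercept = b.theil_sen([0, 1, 2], [0, 1, 0])
    assert (slope, intercept) == (0.0, 0.0)
    with pytest.raises(ValueError):
        b.theil_sen([2, 2, 2], [1, 2, 3])


def test_theil_sen_resists_an_outlier_better_than_least_squares():
    x = np.arange(20.0)
    y = 2.0 * x + 1.0
    x_out = np.append(x, 30.0)
    y_out = np.append(y, 500.0)
    ts_slope, _ = b.theil_sen(x_out, y_out)
    ls_slope = np.polyfit(x_out, y_out, 1)[0]
    assert abs(ts_slope - 2.0) < abs(ls_slope - 2.0)
    assert ts_slope == pytest.approx(2.0, abs=0.2)


def test_theil_sen_equivariance(rng):
    x = rng.normal(size=15)
    y = 3 * x + rng.normal(scale=0.5, size=15)
    slope, intercept = b.theil_sen(x, y)
    slope_c, intercept_c = b.theil_sen(x, y + 7.5)
    assert slope_c == pytest.approx(slope)
    assert intercept_c == pytest.approx(intercept + 7.5)
    slope_k, _ = b.theil_sen(x * 4.0, y)
    assert slope_k == pytest.approx(slope / 4.0)


def profile_with_detection(sample_id, cluster_detected):
    fractions = {fam: 0.0 for fam in b.DEFAULT_FAMILIES}
    return b.SampleProfile(
        sample_id=sample_id, denominator=1000, families=b.DEFAULT_FAMILIES,
        family_counts={fam: 0 for fam in b.DEFAULT_FAMILIES},
        family_fractions=fractions, operon_abundance=1e-9,
        cluster_abundances={1: 1e-6}, cluster_detected={1: cluster_detected},
        cluster_counts={},
    )


def test_prevalence_by_group():
    profiles = [profile_with_detection(f"s{i}", i < 7) for i in range(10)]
    groups = {f"s{i}": "nonIBD" for i in range(10)}
    assert b.prevalence_by_group(profiles, 1, groups) == {"nonIBD": 0.7}
    none = [profile_with_detection(f"s{i}", False) for i in range(5)]
    assert b.prevalence_by_group(none, 1, {f"s{i}": "CD" for i in range(5)}) == {"CD": 0.0}


def test_sample_with_three_families_hit_counts_as_undetected():
    hits = [
        b.ReadHit(f"r{i}", f"s{fam}", fam, "G1", 1.0, 30, 150, cluster_id=1)
        for i, fam in enumerate(b.DEFAULT_FAMILIES[:3])
    ]
    profile = b.build_sample_profile("s1", hits, 1000, clusters=[1])
    assert profile.cluster_detected[1] is False
    assert b.prevalence_by_group([profile], 1, {"s1": "CD"}) == {"CD": 0.0}


def test_mean_abundance_when_detected_is_mean_of_logs():
    profiles = [
        profile_with_detection("a", True),
        profile_with_detection("b", True),
        profile_with_detection("c", False),
    ]
    profiles[0].cluster_abundances[1] = 1e-5
    profiles[1].cluster_abundances[1] = 1e-6
    profiles[2].cluster_abundances[1] = 1e-2  # undetected: must be ignored
    value = b.mean_abundance_when_detected(profiles, 1)
    assert math.log10(value) == pytest.approx(-5.5)
    assert b.mean_abundance_when_detected(profiles[:1], 1) == pytest.approx(1e-5)
    with pytest.raises(ValueError):
        b.mean_abundance_when_detected([profiles[2]], 1)


def flat_profile(level):
    return {fam: level for fam in b.DEFAULT_FAMILIES}


def test_fmt_fold_change_arithmetic():
    series = b.FMTSeries("P1", pre=[flat_profile(1e-8)], post=[flat_profile(1e-6)])
    assert b.fmt_fold_change(series) == pytest.approx(100.0)
    same = b.FMTSeries("P2", pre=[flat_profile(1e-7)], post=[flat_profile(1e-7)])
    assert b.fmt_fold_change(same) == pytest.approx(1.0)
    floored = b.FMTSeries("P3", pre=[flat_profile(0.0)], post=[flat_profile(1e-6)])
    # all-zero pre-FMT profile sits at the 1e-9 pseudocount floor
    assert b.fmt_fold_change(floored) == pytest.approx(1e3)
    with pytest.raises(ValueError):
        b.fmt_fold_change(b.FMTSeries("P4", pre=[], post=[flat_profile(1e-6)]))


def test_fmt_response_association_separation_and_errors():
    folds = [10.0, 20.0, 30.0, 1.0, 0.5, 0.9]
    responses = [True, True, True, False, False, False]
    res = b.fmt_response_association(folds, responses)
    assert res.auc == 1.0
    with pytest.raises(ValueError):
        b.fmt_response_association([1.0, 2.0], [True, True])


def test_fmt_label_permutation_centres_on_half(rng):
    folds = rng.lognormal(0, 1, size=12)
    responses = np.array([True] * 6 + [False] * 6)
    aucs = []
    for _ in range(200):
        perm = rng.permutation(responses)
        aucs.append(b.fmt_response_association(folds, perm).auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)
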