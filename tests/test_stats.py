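"""Nonparametric tests against enumeration oracles; cohort summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from ctcmorph.stats import (
    ComparisonPlan,
    bonferroni_adjust,
    format_p,
    kruskal_wallis,
    mann_whitney_u,
    median_test,
    median_test_table,
    run_comparisons,
    summarize_group,
)

# ---------------------------------------------------------------------------
# oracles


def mwu_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = sps.rankdata(pooled)

    def u_of(idx):
        r1 = sum(ranks[i] for i in idx)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(u <= u_obs for u in us)
    hi = sum(u >= u_obs for u in us)
    return min(1.0, 2 * min(lo, hi) / len(us))


def kw_h_oracle(groups):
    """Kruskal-Wallis H from the rank-mean formula (no ties assumed)."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
    return 12.0 / (n * (n + 1)) * h


# ---------------------------------------------------------------------------
# summaries


def test_summary_hand_computable():
    s = summarize_group([10, 20, 30], "g")
    assert s.median_area == 20 and s.iqr_area == 10
    assert s.cd == pytest.approx(2 * math.sqrt(20 / math.pi))


def test_summary_single_value_and_empty():
    s = summarize_group([42.0], "g")
    assert s.median_area == 42 and s.iqr_area == 0 and s.n == 1
    empty = summarize_group([], "g")
    assert empty.n == 0 and empty.median_area is None


def test_summary_even_count_uses_midpoint():
    s = summarize_group([1.0, 2.0, 3.0, 4.0], "g")
    assert s.median_area == pytest.approx(2.5)


def test_summary_permutation_invariant(rng):
    values = rng.lognormal(4, 0.5, 101)
    s1 = summarize_group(values, "g")
    s2 = summarize_group(rng.permutation(values), "g")
    assert s1 == s2


def test_sample_median_within_order_statistic_interval(rng):
    """The sample median of 10001 lognormal draws stays inside the 99%
    order-statistic interval of the true median."""
    n = 10001
    true_median = 120.4
    draws = rng.lognormal(np.log(true_median), 0.6, n)
    # binomial 99% interval for the number of draws below the true median
    k_lo, k_hi = sps.binom.ppf([0.005, 0.995], n, 0.5).astype(int)
    below = int((draws < true_median).sum())
    assert k_lo <= below <= k_hi
    s = summarize_group(draws, "g")
    lo, hi = np.sort(draws)[[k_lo, k_hi]]
    assert lo <= s.median_area <= hi


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def test_kw_identical_groups_is_null():
    res = kruskal_wallis([[5, 5], [5, 5], [5, 5]])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kw_matches_rank_formula_oracle():
    groups = [[1, 2], [3, 4], [5, 6]]
    res = kruskal_wallis(groups)
    assert res.statistic == pytest.approx(kw_h_oracle(groups))
    assert res.p_value == pytest.approx(float(sps.chi2.sf(res.statistic, 2)))


def test_kw_requires_two_groups():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])


def test_kw_two_groups_equals_squared_mwu_z(rng):
    """Without ties, H for 2 groups equals the square of the MWU z-score."""
    a = rng.normal(0, 1, 30)
    b = rng.normal(0.8, 1, 25)
    h = kruskal_wallis([a, b]).statistic
    u = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", use_continuity=False)
    n1, n2 = len(a), len(b)
    z = (u.statistic - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    assert h == pytest.approx(z * z, rel=1e-9)


def test_kw_type_one_error_calibrated(rng):
    rejections = 0
    reps = 1000
    for _ in range(reps):
        groups = [rng.lognormal(4.0, 0.5, 25) for _ in range(3)]
        if kruskal_wallis(groups).p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / reps <= 0.07


# ---------------------------------------------------------------------------
# Mann-Whitney U


def test_mwu_separated_triples_exact():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2 of the 20 assignments are as extreme


def test_mwu_identical_samples_p_one():
    res = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert res.p_value == pytest.approx(1.0, abs=0.01)


def test_mwu_empty_input_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_mwu_large_shifted_lognormals(rng):
    a = rng.lognormal(np.log(100), 0.5, 500)
    b = rng.lognormal(np.log(150), 0.5, 500)
    assert mann_whitney_u(a, b).p_value < 0.001


@pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 6) for n2 in range(n1, 6) if n1 + n2 <= 10])
def test_mwu_exact_path_equals_enumeration_oracle(n1, n2, rng):
    for _ in range(3):
        pooled = rng.permutation(rng.uniform(0, 100, n1 + n2))
        a, b = pooled[:n1], pooled[n1:]
        res = mann_whitney_u(a, b)
        assert res.p_value == pytest.approx(mwu_exact_oracle(a, b), abs=1e-12)


# ---------------------------------------------------------------------------
# median test


def test_median_test_identical_groups():
    res = median_test([[1, 2, 3, 4], [1, 2, 3, 4]])
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_median_test_same_composition_statistic_zero():
    res = median_test([[1, 1, 1, 9, 9, 9], [9, 9, 9, 1, 1, 1]])
    assert res.statistic == pytest.approx(0.0)


def test_median_test_degenerate_is_undefined():
    res = median_test([[5, 5, 5], [5, 5, 5]])
    assert res.statistic is None and res.p_value is None


def test_median_test_contingency_matches_bruteforce(rng):
    for _ in range(10):
        groups = [rng.integers(0, 20, rng.integers(3, 12)).astype(float) for _ in range(3)]
        table = median_test_table(groups)
        grand = np.median(np.concatenate(groups))
        expected = np.array(
            [[int((g > grand).sum()) for g in groups], [int((g <= grand).sum()) for g in groups]]
        )
        assert (table == expected).all()


# ---------------------------------------------------------------------------
# comparison plan


def _cohorts(rng, with_optional=True):
    samples = {
        "breast_blood": rng.lognormal(np.log(120.4), 0.6, 150),
        "prostate_blood": rng.lognormal(np.log(83.6), 0.55, 120),
        "colorectal_blood": rng.lognormal(np.log(44.6), 0.8, 60),
        "bladder_blood": rng.lognormal(np.log(57.8), 1.0, 50),
    }
    if with_optional:
        samples.update(
            {
                "breast_liquor": rng.lognormal(np.log(141.3), 0.6, 60),
                "breast_cell_line_blood": rng.lognormal(np.log(265.4), 0.35, 80),
                "prostate_cell_line_blood": rng.lognormal(np.log(337.9), 0.3, 70),
                "leukocyte_blood": rng.lognormal(np.log(69.6), 0.27, 50),
            }
        )
    return samples


def test_full_plan_produces_expected_battery(rng):
    results = run_comparisons(_cohorts(rng))
    by_test = {}
    for r in results:
        by_test.setdefault(r.test, []).append(r)
    assert len(by_test["kruskal_wallis"]) == 1
    assert len(by_test["median_test"]) == 1
    # 6 pairwise tumor + liquor + 2 cell lines + 4 leukocyte
    assert len(by_test["mann_whitney_u"]) == 13


def test_missing_liquor_cohort_skipped_with_warning(rng):
    samples = _cohorts(rng)
    samples.pop("breast_liquor")
    with pytest.warns(UserWarning, match="breast_liquor"):
        results = run_comparisons(samples)
    assert len([r for r in results if r.test == "mann_whitney_u"]) == 12


def test_missing_required_cohort_raises(rng):
    samples = _cohorts(rng)
    samples.pop("prostate_blood")
    with pytest.raises(ValueError, match="prostate_blood"):
        run_comparisons(samples)


def test_null_cohorts_give_uniformish_pvalues(rng):
    """With all cohorts drawn from one distribution, the pairwise MWU stage
    rejects at roughly its nominal rate."""
    rejected = total = 0
    for _ in range(150):
        samples = {
            name: rng.lognormal(4.0, 0.5, 40)
            for name in ("breast_blood", "prostate_blood", "colorectal_blood", "bladder_blood")
        }
        plan = ComparisonPlan(liquor_pairs=(), cell_line_pairs=(), leukocyte_cohort=None,
                              include_median_test=False)
        for r in run_comparisons(samples, plan):
            if r.test == "mann_whitney_u":
                total += 1
                rejected += r.p_value < 0.05
    assert 0.02 <= rejected / total <= 0.08


def test_bonferroni_adjustment_scales_p():
    from ctcmorph.stats import TestResult

    results = [
        TestResult("mann_whitney_u", ("a", "b"), 1.0, 0.01, (5, 5)),
        TestResult("mann_whitney_u", ("a", "c"), 1.0, 0.9, (5, 5)),
    ]
    adjusted = bonferroni_adjust(results)
    assert adjusted[0].p_value == pytest.approx(0.02)
    assert adjusted[1].p_value == 1.0


def test_p_value_formatting():
    assert format_p(0.0005) == "< 0.001"
    assert format_p(0.0312) == "0.031"
    assert format_p(None) == "undefined"
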