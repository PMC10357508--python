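from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from coroflow.physiology import apply_exclusions
from coroflow.stats import (StatError, anova, chi_square_test, correlation,
                            effect_size, hedges_correction,
                            kruskal_wallis_test, normality_test,
                            rank_sum_test, subgroup_report, summarize,
                            t_test)
from coroflow.synthetic_cohort import GeneratorConfig, generate_cohort


# ------------------------------------------------------------- Shapiro-Wilk
def test_shapiro_rejects_degenerate_input():
    with pytest.raises(StatError):
        normality_test([3.0] * 10)
    with pytest.raises(StatError):
        normality_test([1.0, 2.0])          # n < 3


def test_shapiro_calibration_under_normal_and_lognormal():
    """Gaussian samples rarely rejected; strongly skewed samples almost
    always rejected at n = 200."""
    keep, reject = 0, 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        _, p_norm = normality_test(rng.normal(size=200))
        _, p_logn = normality_test(rng.lognormal(0.0, 1.0, size=200))
        keep += p_norm > 0.05
        reject += p_logn < 0.05
    assert keep >= 90
    assert reject >= 95


# -------------------------------------------------------------- Mann-Whitney
def test_rank_sum_fully_separated_toy():
    """x={1,2,3} vs y={4,5,6}: U = 0 and the exact two-sided p is
    2/20 = 0.10 (enumeration over C(6,3) assignments)."""
    res = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_exact == pytest.approx(0.10)
    # independent brute force in-test
    pooled = np.arange(1, 7)
    count = sum(1 for idx in combinations(range(6), 3)
                if abs(sum(pooled[list(idx)]) - 10.5) >= abs(6 - 10.5))
    assert count / 20 == pytest.approx(res.p_exact)


def test_rank_sum_symmetry_and_antisymmetry(rng):
    x = rng.normal(size=30)
    same = rank_sum_test(x, x.copy())
    assert abs(same.z) < 1e-9
    assert same.p == pytest.approx(1.0)
    y = rng.normal(1.0, 1.0, size=25)
    ab = rank_sum_test(x, y)
    ba = rank_sum_test(y, x)
    assert ab.z == pytest.approx(-ba.z, rel=1e-9)
    assert ab.p == pytest.approx(ba.p, rel=1e-9)


def test_rank_sum_sign_convention(rng):
    """Z > 0 when the second (comparison) group tends to larger values."""
    low = rng.normal(0.0, 1.0, 40)
    high = rng.normal(2.0, 1.0, 40)
    assert rank_sum_test(low, high).z > 0
    assert rank_sum_test(high, low).z < 0


def test_rank_sum_normal_approx_close_to_exact():
    """Tie-free samples with n_x = n_y in {5, 6}: the continuity-corrected
    normal approximation is within 0.02 of the exact permutation p."""
    for seed in range(50):
        rng = np.random.default_rng(seed)
        for n in (5, 6):
            x = rng.normal(size=n)
            y = rng.normal(0.5, 1.0, size=n)
            res = rank_sum_test(x, y)
            assert res.p_exact is not None
            assert abs(res.p - res.p_exact) <= 0.02


def test_rank_sum_matches_scipy(rng):
    """Cross-check the hand-rolled U and p against scipy (asymptotic mode
    with continuity correction), including ties."""
    for _ in range(20):
        x = np.round(rng.normal(size=18), 1)   # rounding induces ties
        y = np.round(rng.normal(0.3, 1.0, size=14), 1)
        res = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_rank_based_p_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(0.4, 1.2, size=9)
    base = rank_sum_test(x, y)
    for f in (np.exp, lambda v: v ** 3, lambda v: 2 * v + 7):
        res = rank_sum_test(f(x), f(y))
        assert res.p == pytest.approx(base.p, rel=1e-12)
        assert res.statistic == pytest.approx(base.statistic)


# ------------------------------------------------------------ Kruskal-Wallis
def test_kruskal_two_groups_redirects():
    with pytest.raises(StatError, match="rank_sum_test"):
        kruskal_wallis_test([1, 2], [3, 4])


def test_kruskal_degenerate_error():
    with pytest.raises(StatError):
        kruskal_wallis_test([1.0, 1.0], [1.0, 1.0], [1.0, 1.0])


def test_kruskal_toy_matches_exact_permutation():
    """3 groups of 4: chi-square p within 0.03 of the exact permutation
    distribution of H (full enumeration of 34,650 arrangements)."""
    groups = [[1.2, 3.4, 2.2, 5.1], [2.8, 4.9, 6.0, 3.9],
              [7.1, 6.5, 8.2, 4.4]]
    res = kruskal_wallis_test(*groups)

    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = 12

    def h_stat(r1, r2, r3):
        ssq = sum(r.sum() ** 2 / 4 for r in (r1, r2, r3))
        return 12.0 / (n * (n + 1)) * ssq - 3 * (n + 1)

    h_obs = h_stat(ranks[:4], ranks[4:8], ranks[8:])
    assert res.statistic == pytest.approx(h_obs)

    idx_all = set(range(n))
    count = total = 0
    for g1 in combinations(range(n), 4):
        rest = sorted(idx_all - set(g1))
        for g2 in combinations(rest, 4):
            g3 = sorted(set(rest) - set(g2))
            h = h_stat(ranks[list(g1)], ranks[list(g2)], ranks[g3])
            total += 1
            count += h >= h_obs - 1e-12
    assert total == 34650
    p_exact = count / total
    assert abs(res.p - p_exact) <= 0.03


# ---------------------------------------------------------------- chi-square
def test_chi_square_independence_and_scaling():
    res = chi_square_test([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(1.0)
    base = chi_square_test([[12, 5], [7, 9]])
    doubled = chi_square_test([[24, 10], [14, 18]])
    assert doubled.statistic == pytest.approx(2 * base.statistic)


def test_chi_square_hand_computed():
    """[[20,5],[5,20]]: all expected counts are 12.5, so
    chi2 = 4 * 7.5^2 / 12.5 = 18."""
    res = chi_square_test([[20, 5], [5, 20]])
    assert res.statistic == pytest.approx(18.0)


def test_chi_square_zero_marginal():
    with pytest.raises(StatError):
        chi_square_test([[0, 0], [5, 10]])


# -------------------------------------------------------------- t test/ANOVA
def test_t_identical_groups():
    res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_two_group_anova_equals_pooled_t_squared(rng):
    x = rng.normal(size=12)
    y = rng.normal(0.7, 1.0, size=15)
    f = anova(x, y)
    t = t_test(x, y, equal_var=True)
    assert f.statistic == pytest.approx(t.statistic ** 2, rel=1e-10)
    assert f.p == pytest.approx(t.p, rel=1e-10)


def test_welch_t_hand_computed():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([3.0, 5.0, 7.0, 9.0])
    res = t_test(x, y)
    se = np.sqrt(np.var(x, ddof=1) / 4 + np.var(y, ddof=1) / 4)
    assert res.statistic == pytest.approx((x.mean() - y.mean()) / se)


# -------------------------------------------------------------- effect sizes
def test_effect_sizes_identities(rng):
    x = rng.normal(size=20)
    y = rng.normal(0.5, 1.0, size=25)
    d = effect_size(x, y, "cohen_d")
    g = effect_size(x, y, "hedges_g")
    assert g / d == pytest.approx(hedges_correction(43))
    assert hedges_correction(43) == pytest.approx(1 - 3 / (4 * 43 - 1))
    assert effect_size(y, x, "cohen_d") == pytest.approx(-d)
    assert effect_size(x, x.copy(), "cohen_d") == 0.0


# --------------------------------------------------------------- correlation
def test_correlation_exact_lines():
    x = np.array([1.0, 2.0, 4.0, 5.5, 9.0])
    assert correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert correlation(x, -x)[0] == pytest.approx(-1.0)


def test_correlation_hand_computed():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
    r, p = correlation(x, y)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    expected = cov / (np.std(x) * np.std(y))
    assert r == pytest.approx(expected)
    assert 0.0 < p < 1.0


# ----------------------------------------------------------- subgroup report
def _cohort_results(seed, n_male=50, n_female=50, medians=None):
    medians = medians or {"male": 680.0, "female": 680.0}
    cfg = GeneratorConfig(n_male=n_male, n_female=n_female, seed=seed,
                          cmvr_hyper_median_wu=medians,
                          severity_mean_pct=65.0, severity_sd_pct=5.0,
                          r0_mean_mm=1.2, r0_sd_mm=0.15,
                          projection_noise_sd_mm=0.0)
    cohort = generate_cohort(cfg, with_projections=False)
    results, _, _ = apply_exclusions(cohort.cases)
    return results


def test_subgroup_report_structure_and_errors():
    results = _cohort_results(seed=1)
    report = subgroup_report(results, ["sex", "smoker", "artery",
                                       "artery_origin", "age"])
    assert list(report["variable"]) == ["sex", "smoker", "artery",
                                        "artery_origin", "age"]
    assert report["p"].between(0, 1).all()
    with pytest.raises(StatError):
        subgroup_report(results, ["no_such_variable"])
    single = results[results.sex == "male"]
    with pytest.raises(StatError, match="single level"):
        subgroup_report(single, ["sex"])


def test_subgroup_null_cohorts_type_one_error():
    """No sex effect: the sex row rejects at roughly the nominal rate
    (200 seeded cohorts; binomial bounds around 0.05)."""
    hits = 0
    for seed in range(200):
        results = _cohort_results(seed=seed)
        report = subgroup_report(results, ["sex"])
        hits += bool(report["significant"].iloc[0])
    assert 2 <= hits <= 20          # ~0.05 * 200 = 10 expected


def test_subgroup_detects_injected_sex_effect():
    """Study-size cohorts at the sex-specific default medians: the sex row
    flags in the majority of seeds, null covariates only at chance rate."""
    sex_hits = 0
    other_hits = []
    for seed in range(20):
        results = _cohort_results(
            seed=1000 + seed, n_male=109, n_female=35,
            medians={"male": 680.0, "female": 860.0})
        report = subgroup_report(results, ["sex", "smoker", "diabetes"])
        sex_hits += bool(report["significant"].iloc[0])
        other_hits.append(report["significant"].iloc[1:].sum())
    assert sex_hits >= 12
    assert sum(other_hits) <= 10


def test_summaries_follow_normality_gate(rng):
    normal = rng.normal(100.0, 10.0, 300)
    skewed = rng.lognormal(4.0, 0.8, 300)
    assert "±" in summarize(normal)
    assert "[" in summarize(skewed)
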