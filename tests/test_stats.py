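"""First-principles statistics against brute-force and library oracles.

Each procedure is checked two ways: against a literal re-evaluation of
its defining formula (rank-then-Pearson, sum (O-E)^2/E, explicit sums of
squares) and against the corresponding scipy routine on fuzzed inputs.
"""

import math

import numpy as np
import pytest
import scipy.stats

from riskspectra.stats import anova_binary, chi2_2x2, chi2_gof, midranks, spearman


def brute_spearman(x, y):
    """Oracle: Pearson correlation applied to average ranks."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def brute_anova_f(y, groups):
    """Oracle: explicit between/within sums of squares."""
    y = np.asarray(y, dtype=float)
    labels = sorted(set(groups))
    grand = y.mean()
    ss_b = ss_w = 0.0
    for lab in labels:
        sub = y[[g == lab for g in groups]]
        ss_b += len(sub) * (sub.mean() - grand) ** 2
        ss_w += ((sub - sub.mean()) ** 2).sum()
    df_b, df_w = len(labels) - 1, len(y) - len(labels)
    return (ss_b / df_b) / (ss_w / df_w)


def test_midranks_average_ties():
    assert midranks([10, 20, 20, 30]).tolist() == [1.0, 2.5, 2.5, 4.0]


def test_spearman_perfect_and_reversed():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    assert spearman(x, x).statistic == pytest.approx(1.0)
    assert spearman(x, x[::-1]).statistic == pytest.approx(-1.0)
    assert spearman(x, x).p_value == pytest.approx(0.0, abs=1e-12)


def test_spearman_matches_brute_force_and_scipy():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(3, 40))
        x = rng.integers(0, 6, size=n).astype(float)  # plenty of ties
        y = rng.normal(size=n)
        if np.all(x == x[0]):
            continue
        res = spearman(x, y)
        assert res.statistic == pytest.approx(brute_spearman(x, y), abs=1e-12)
        rho_sp, p_sp = scipy.stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(rho_sp, abs=1e-10)
        if abs(res.statistic) < 1.0:
            assert res.p_value == pytest.approx(p_sp, abs=1e-8)


def test_spearman_monotone_invariance():
    rng = np.random.default_rng(5)
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    base = spearman(x, y).statistic
    assert spearman(np.exp(x), y).statistic == pytest.approx(base, abs=1e-12)
    assert spearman(x, 3 * y + 7).statistic == pytest.approx(base, abs=1e-12)
    assert spearman(-x, y).statistic == pytest.approx(-base, abs=1e-12)


def test_spearman_degenerate_reports_not_computable():
    res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert not res.computable and math.isnan(res.statistic)


def test_spearman_exact_permutation_small_n():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
    res = spearman(x, y, exact=True)
    # enumerate all 6! permutations independently
    import itertools

    observed = abs(brute_spearman(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(brute_spearman(x, perm)) >= observed - 1e-12:
            hits += 1
    assert res.p_value == pytest.approx(hits / total)


def test_chi2_gof_zero_at_expectation():
    res = chi2_gof([25, 25, 25, 25], [0.25] * 4)
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_chi2_gof_matches_direct_formula_and_scipy():
    rng = np.random.default_rng(3)
    for _ in range(100):
        k = int(rng.integers(2, 8))
        props = rng.dirichlet(np.ones(k) * 2)
        obs = rng.integers(1, 200, size=k)
        expected = obs.sum() * props
        stat_oracle = float(((obs - expected) ** 2 / expected).sum())
        res = chi2_gof(obs, props)
        assert res.statistic == pytest.approx(stat_oracle, abs=1e-10)
        stat_sp, p_sp = scipy.stats.chisquare(obs, expected)
        assert res.statistic == pytest.approx(stat_sp, abs=1e-9)
        assert res.p_value == pytest.approx(p_sp, abs=1e-10)


def test_chi2_2x2_hand_built_table():
    # ((10,90),(20,80)): margins 30/170/100/100, expected ((15,85),(15,85))
    stat = 25 / 15 + 25 / 85 + 25 / 15 + 25 / 85
    res = chi2_2x2([[10, 90], [20, 80]])
    assert res.statistic == pytest.approx(stat, abs=1e-12)
    assert res.df == 1


def test_chi2_2x2_matches_scipy_without_correction():
    rng = np.random.default_rng(9)
    for _ in range(100):
        table = rng.integers(1, 500, size=(2, 2))
        res = chi2_2x2(table)
        stat, p, df, _ = scipy.stats.chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-10)


def test_chi2_2x2_equals_squared_two_proportion_z():
    n1, k1, n2, k2 = 400, 30, 600, 60
    res = chi2_2x2([[k1, n1 - k1], [k2, n2 - k2]])
    p_pool = (k1 + k2) / (n1 + n2)
    z = (k1 / n1 - k2 / n2) / math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    assert res.statistic == pytest.approx(z * z, abs=1e-10)


def test_chi2_identical_proportions_give_zero():
    res = chi2_2x2([[10, 90], [10, 90]])
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_anova_two_group_example_by_hand():
    y = [1, 1, 0, 0, 1, 0, 0, 0]
    groups = ["a"] * 4 + ["b"] * 4
    res = anova_binary(y, groups)
    assert res.statistic == pytest.approx(brute_anova_f(y, groups), abs=1e-12)
    assert res.df == (1, 6)


def test_anova_matches_oracle_and_scipy_on_fuzz():
    rng = np.random.default_rng(21)
    checked = 0
    while checked < 100:
        k = int(rng.integers(2, 6))
        sizes = rng.integers(3, 15, size=k)
        y = np.concatenate([rng.integers(0, 2, size=s) for s in sizes]).astype(float)
        groups = np.concatenate([[f"g{i}"] * s for i, s in enumerate(sizes)])
        res = anova_binary(y, groups)
        if not res.computable or res.statistic == 0.0:
            continue
        assert res.statistic == pytest.approx(brute_anova_f(y, groups), abs=1e-10)
        f_sp, p_sp = scipy.stats.f_oneway(*[y[groups == f"g{i}"] for i in range(k)])
        assert res.statistic == pytest.approx(f_sp, abs=1e-9)
        assert res.p_value == pytest.approx(p_sp, abs=1e-10)
        checked += 1


def test_anova_zero_between_group_variance_gives_zero_f():
    y = [1, 0, 1, 0, 1, 0]
    res = anova_binary(y, ["a", "a", "b", "b", "c", "c"])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_two_groups_is_t_squared():
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, size=40).astype(float)
    groups = np.array(["a"] * 22 + ["b"] * 18)
    res = anova_binary(y, groups)
    t, _ = scipy.stats.ttest_ind(y[groups == "a"], y[groups == "b"], equal_var=True)
    assert res.statistic == pytest.approx(t * t, abs=1e-10)


def test_anova_rejects_degenerate_grouping():
    with pytest.raises(ValueError):
        anova_binary([1, 0], ["a", "b"])  # all groups size 1
    with pytest.raises(ValueError):
        anova_binary([1, 0, 1], ["a", "a", "a"])  # single group
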