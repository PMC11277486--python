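"""Runs test, rate regression, pruning, and ADD-accumulation validation."""

import itertools

import numpy as np
import pytest

from thermaldev.degreeday import (
    DevelopmentRateModel,
    fit_validated_degree_day_model,
    prune_until_linear,
    rate_regression,
    runs_distribution,
    runs_test,
    summarize_add,
)


# ----------------------------------------------------------------------
# Runs test: exact distribution against brute-force enumeration
# ----------------------------------------------------------------------
def _count_runs(signs):
    return 1 + sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def _brute_force_pmf(n_pos, n_neg):
    """Runs distribution by explicit enumeration of every arrangement."""
    n = n_pos + n_neg
    pmf = np.zeros(n + 1)
    arrangements = 0
    for pos_slots in itertools.combinations(range(n), n_pos):
        signs = [-1] * n
        for i in pos_slots:
            signs[i] = 1
        pmf[_count_runs(signs)] += 1
        arrangements += 1
    return pmf / arrangements


@pytest.mark.parametrize("n_pos,n_neg", [(1, 1), (2, 3), (4, 4), (3, 5), (5, 5), (2, 6)])
def test_closed_form_runs_distribution_matches_enumeration(n_pos, n_neg):
    np.testing.assert_allclose(
        runs_distribution(n_pos, n_neg), _brute_force_pmf(n_pos, n_neg), atol=1e-12
    )


def test_exact_p_values_match_enumeration_for_all_small_patterns():
    """Every sign pattern with n <= 10 residuals: the reported two-sided
    p-value equals the one computed from the brute-force distribution."""
    for n in range(2, 11):
        for bits in itertools.product([1.0, -1.0], repeat=n):
            res = runs_test(bits)
            if res.n_pos == 0 or res.n_neg == 0:
                assert res.p_value == 1.0
                continue
            pmf = _brute_force_pmf(res.n_pos, res.n_neg)
            lower = pmf[: res.runs + 1].sum()
            upper = pmf[res.runs:].sum()
            expected = min(1.0, 2.0 * min(lower, upper))
            assert res.p_value == pytest.approx(expected, abs=1e-12)


def test_single_sign_change_pattern_probability():
    """++++---- has two runs; among the 70 arrangements of four of each
    sign, exactly two have R <= 2, a one-tail probability of 2/70."""
    res = runs_test([1.0] * 4 + [-1.0] * 4)
    assert res.runs == 2
    pmf = runs_distribution(4, 4)
    assert pmf[2] == pytest.approx(2.0 / 70.0)
    assert res.p_value == pytest.approx(2.0 * 2.0 / 70.0)


def test_perfectly_alternating_signs_is_upper_tail_extreme():
    res = runs_test([1.0, -1.0] * 5)
    assert res.runs == 10
    assert res.p_value == pytest.approx(2.0 * runs_distribution(5, 5)[10])
    assert res.p_value < 0.02


def test_all_one_sign_is_degenerate_but_computed():
    res = runs_test([0.5, 0.2, 0.9])
    assert res.runs == 1
    assert res.p_value == 1.0
    assert res.method == "degenerate"


def test_zero_residuals_dropped_before_counting():
    res = runs_test([1.0, 0.0, -1.0, 0.0, 1.0])
    assert res.n == 3
    assert res.runs == 3


def test_runs_test_needs_two_nonzero_residuals():
    with pytest.raises(ValueError):
        runs_test([0.0, 0.0, 1.0])


def test_normal_approximation_close_to_exact_beyond_cutoff():
    signs = [1.0] * 12 + [-1.0] * 13
    exact = runs_test(signs, exact_max=30)
    approx = runs_test(signs, exact_max=20)
    assert approx.method == "normal" and exact.method == "exact"
    assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)


# ----------------------------------------------------------------------
# Rate regression
# ----------------------------------------------------------------------
def test_constructed_linear_rates_recover_exactly():
    T = np.array([15.0, 20.0, 25.0, 30.0])
    res = rate_regression(T, 0.01 * (T - 10.0), event="demo")
    assert res.dev_min == pytest.approx(10.0, abs=1e-9)
    assert res.add == pytest.approx(100.0, rel=1e-9)
    assert res.r2 == pytest.approx(1.0)
    # exact algebraic identities of the parameterisation
    assert res.add * res.slope == pytest.approx(1.0, rel=1e-12)
    assert res.dev_min == pytest.approx(-res.intercept / res.slope, rel=1e-12)


def test_too_few_points_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        rate_regression([15.0, 20.0], [0.05, 0.10])


def test_no_thermal_response_rejected():
    T = np.array([15.0, 20.0, 25.0, 30.0])
    with pytest.raises(ValueError, match="slope"):
        rate_regression(T, 0.2 - 0.004 * T)


def test_nonpositive_rates_rejected():
    with pytest.raises(ValueError, match="positive"):
        DevelopmentRateModel([15.0, 20.0, 25.0], [0.1, -0.1, 0.2])


# ----------------------------------------------------------------------
# Pruning
# ----------------------------------------------------------------------
def test_already_linear_data_is_a_fixed_point():
    rng = np.random.default_rng(11)
    T = np.arange(15.0, 33.0, 2.5)
    rate = 0.011 * (T - 9.8) + rng.normal(0.0, 1e-4, T.size)
    plain = rate_regression(T, rate)
    pruned = prune_until_linear(T, rate)
    assert pruned.exclusions == []
    assert pruned.slope == pytest.approx(plain.slope)
    np.testing.assert_array_equal(pruned.temperatures, plain.temperatures)


def test_strong_low_end_curvature_is_excluded_exactly():
    """Rates linear on 15-32.5 degC with strong downward curvature below
    15 degC: pruning removes exactly the curved temperatures, low end first,
    and the refit recovers the generating line."""
    T = np.arange(12.5, 32.6, 1.25)
    rate = 0.01 * (T - 10.2)
    rate[T < 15.0] *= np.array([0.375, 0.6875])
    res = prune_until_linear(T, rate)
    assert [e["temperature"] for e in res.exclusions] == [12.5, 13.75]
    assert res.temperature_range == (15.0, 32.5)
    assert res.dev_min == pytest.approx(10.2, abs=1e-6)
    assert res.add == pytest.approx(100.0, rel=1e-6)


def test_pruning_only_shrinks_and_refit_is_stable():
    T = np.arange(12.5, 32.6, 1.25)
    rate = 0.01 * (T - 10.2)
    rate[T < 15.0] *= np.array([0.2, 0.6])
    res = prune_until_linear(T, rate)
    assert set(res.temperatures) < set(T)
    again = prune_until_linear(res.temperatures, res.rates)
    assert again.exclusions == []
    np.testing.assert_array_equal(again.temperatures, res.temperatures)


def test_pruning_requires_four_points():
    with pytest.raises(ValueError, match="at least 4"):
        prune_until_linear([15.0, 20.0, 25.0], [0.05, 0.1, 0.15])


# ----------------------------------------------------------------------
# Validation loop and ADD summary
# ----------------------------------------------------------------------
def test_clean_linear_durations_accepted_with_flat_accumulation():
    T = np.arange(15.0, 33.0, 2.5)
    days = 100.0 / (T - 10.0)  # exact: ADD 100, dev_min 10
    res = fit_validated_degree_day_model(T, days, event="demo")
    v = res.validation
    assert v["accepted"]
    assert v["acc_slope"] == pytest.approx(0.0, abs=1e-9)
    assert v["add_mean"] == pytest.approx(100.0, rel=1e-9)
    assert v["add_sd"] == pytest.approx(0.0, abs=1e-6)
    assert res.exclusions == []


def test_validated_fit_excludes_curved_temperatures_end_to_end():
    T = np.arange(12.5, 32.6, 1.25)
    rate = 0.012 * (T - 10.5)
    rate[T < 15.0] *= np.array([0.3, 0.65])
    res = fit_validated_degree_day_model(T, 1.0 / rate, event="demo")
    assert sorted(e["temperature"] for e in res.exclusions) == [12.5, 13.75]
    assert res.dev_min == pytest.approx(10.5, abs=1e-6)
    assert res.validation["accepted"]


def test_summarize_add_mean_and_population_sd():
    vals = [191.2, 184.1, 181.5, 175.3, 172.8, 179.9]
    s = summarize_add(vals, regression_add=181.9)
    assert s["add_mean"] == pytest.approx(180.8, abs=0.05)
    assert s["add_sd"] == pytest.approx(5.98, abs=0.01)
    assert round(s["add_sd"], 1) == 6.0
    assert s["pct_deviation"] == pytest.approx(100 * (s["add_mean"] - 181.9) / 181.9)


def test_summarize_add_degenerate_cases():
    s = summarize_add([7.0, 7.0, 7.0])
    assert s["add_mean"] == 7.0 and s["add_sd"] == 0.0
    with pytest.raises(ValueError):
        summarize_add([])
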