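"""Permutation tests, correlations, partial correlation, geography."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from campkin import (
    camp_pair_analysis,
    correlation,
    haversine_km,
    partial_correlation,
    permutation_test,
)
from campkin.pedigree import RelatednessMatrix


def exhaustive_permutation_p(values, labels):
    """Oracle: enumerate every assignment of the label multiset."""
    values = np.asarray(values, float)
    labels = list(labels)
    la, lb = sorted(set(labels))
    n_a = labels.count(la)
    idx = range(len(values))
    obs = values[[l == la for l in labels]].mean() - \
        values[[l == lb for l in labels]].mean()
    count = total = 0
    for combo in itertools.combinations(idx, n_a):
        mask = np.zeros(len(values), bool)
        mask[list(combo)] = True
        stat = values[mask].mean() - values[~mask].mean()
        total += 1
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    return count / total


def test_identical_groups_give_p_one():
    res = permutation_test([1.0, 1.0, 1.0, 1.0], ["A", "A", "B", "B"],
                           n_permutations=999, seed=0)
    assert res.observed_difference == 0.0
    assert res.p_two_tailed == 1.0


def test_sampled_p_matches_exhaustive_enumeration():
    values = [10.0, 10.0, 10.0, 0.0, 0.0, 0.0]
    labels = ["A"] * 3 + ["B"] * 3
    exact = exhaustive_permutation_p(values, labels)
    assert exact == pytest.approx(2 / 20)
    res = permutation_test(values, labels, n_permutations=20_000, seed=1)
    # add-one-corrected sampled estimate within Monte-Carlo error
    se = math.sqrt(exact * (1 - exact) / 20_000)
    assert abs(res.p_two_tailed - exact) <= 4 * se + 1e-4


def test_sampled_p_matches_enumeration_on_random_data():
    rng = np.random.default_rng(9)
    values = rng.normal(size=9)
    labels = ["A"] * 4 + ["B"] * 5
    exact = exhaustive_permutation_p(values, labels)
    res = permutation_test(values, labels, n_permutations=30_000, seed=2)
    se = math.sqrt(exact * (1 - exact) / 30_000)
    assert abs(res.p_two_tailed - exact) <= 4 * se + 1e-4


def test_p_values_uniform_under_iid_null():
    """Sampling two groups from one distribution must give uniform p."""
    pvals = []
    rng = np.random.default_rng(123)
    for k in range(300):
        v = rng.normal(size=20)
        labels = ["A"] * 11 + ["B"] * 9
        pvals.append(
            permutation_test(v, labels, n_permutations=199, seed=k)
            .p_two_tailed
        )
    stat, p = sps.kstest(pvals, "uniform")
    assert p > 0.01


def test_permutation_seed_reproducibility():
    v = list(np.random.default_rng(5).normal(size=12))
    labels = ["A"] * 6 + ["B"] * 6
    r1 = permutation_test(v, labels, n_permutations=500, seed=77)
    r2 = permutation_test(v, labels, n_permutations=500, seed=77)
    assert r1 == r2


def test_one_empty_group_errors():
    with pytest.raises(ValueError):
        permutation_test([1.0, 2.0], ["A", "A"], 10, 0)


# -- correlations -----------------------------------------------------------

def test_pearson_perfect_line():
    x = np.arange(10.0)
    coef, p = correlation(x, 2 * x + 1)
    assert coef == pytest.approx(1.0)


def test_spearman_monotone_nonlinear():
    x = np.arange(1.0, 13.0)
    y = np.exp(x)
    rho, _ = correlation(x, y, method="spearman")
    pear, _ = correlation(x, y, method="pearson")
    assert rho == pytest.approx(1.0)
    assert pear < 1.0


def test_pearson_matches_textbook_formula():
    rng = np.random.default_rng(4)
    x = rng.normal(size=10)
    y = 0.5 * x + rng.normal(size=10)
    coef, _ = correlation(x, y)
    oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
        x.std() * y.std()
    )
    assert coef == pytest.approx(oracle, abs=1e-12)


def test_spearman_small_n_exact_p_matches_enumeration_definition():
    x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
    y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
    rho, p = correlation(x, y, method="spearman")
    # classical formula: rho = 1 - 6*sum(d^2)/(n(n^2-1)), here sum(d^2) = 6
    assert rho == pytest.approx(1 - 6 * 6 / (6 * 35))
    assert 0 < p <= 1


def test_zero_variance_is_error():
    with pytest.raises(ValueError, match="variance"):
        correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# -- partial correlation ----------------------------------------------------

def test_partial_equals_residual_correlation_oracle():
    rng = np.random.default_rng(21)
    for _ in range(5):
        z = rng.normal(size=30)
        x = 0.6 * z + rng.normal(size=30)
        y = -0.4 * z + rng.normal(size=30)
        coef, _ = partial_correlation(x, y, z)
        # regress x and y on z, correlate the residuals
        bx = np.polyfit(z, x, 1)
        by = np.polyfit(z, y, 1)
        rx = x - np.polyval(bx, z)
        ry = y - np.polyval(by, z)
        oracle = sps.pearsonr(rx, ry).statistic
        assert coef == pytest.approx(oracle, abs=1e-10)


def test_partial_close_to_raw_when_z_independent():
    rng = np.random.default_rng(3)
    x = rng.normal(size=4000)
    y = 0.5 * x + rng.normal(size=4000)
    z = rng.normal(size=4000)
    raw, _ = correlation(x, y)
    part, _ = partial_correlation(x, y, z)
    assert part == pytest.approx(raw, abs=0.02)


def test_partial_degenerate_collinear_error():
    z = np.arange(10.0)
    with pytest.raises(ValueError, match="degenerate|collinear"):
        partial_correlation(z, z, z)


# -- geography --------------------------------------------------------------

def test_haversine_analytic_values():
    assert haversine_km((10.0, 20.0), (10.0, 20.0)) == 0.0
    half_circumference = math.pi * 6371.0088
    assert haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
        half_circumference, abs=0.01)
    one_degree = 2 * math.pi * 6371.0088 / 360
    assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
        one_degree, abs=0.001)


def test_haversine_rejects_bad_coordinates():
    with pytest.raises(ValueError):
        haversine_km((91.0, 0.0), (0.0, 0.0))


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    pts=st.lists(
        st.tuples(st.floats(-90, 90), st.floats(-180, 180)),
        min_size=3, max_size=3,
    )
)
def test_haversine_symmetry_and_triangle_inequality(pts):
    a, b, c = pts
    assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))
    assert haversine_km(a, c) <= haversine_km(a, b) + haversine_km(b, c) \
        + 1e-6


# -- camp pairs -------------------------------------------------------------

def test_camp_pair_table_has_all_unordered_pairs(default_population,
                                                 default_relatedness):
    ped, panel = default_population
    adults = [i for i, rec in ped.records.items() if rec.is_adult]
    table, (rho, p) = camp_pair_analysis(
        default_relatedness, panel.memberships, panel.coordinates,
        include=adults)
    n_camps = len(panel.camps())
    assert len(table) == n_camps * (n_camps - 1) // 2 == 105
    assert (table["distance_km"] >= 0).all()


def test_cloned_camp_cross_mean_equals_within_mean():
    ids = [f"a{k}" for k in range(4)] + [f"b{k}" for k in range(4)] \
        + ["x0", "x1"]
    n = len(ids)
    vals = np.zeros((n, n))
    vals[:8, :8] = 0.3
    np.fill_diagonal(vals, np.nan)
    r = RelatednessMatrix(ids, vals)
    memberships = {i: ("A" if i.startswith("a") else
                       "B" if i.startswith("b") else "C") for i in ids}
    coords = {"A": (10.0, 20.0), "B": (10.0, 20.0), "C": (11.0, 20.0)}
    table, _ = camp_pair_analysis(r, memberships, coords)
    row = table[(table.camp_a == "A") & (table.camp_b == "B")].iloc[0]
    assert row["mean_r"] == pytest.approx(0.3)
    assert row["distance_km"] == 0.0


def test_camp_without_coordinates_excluded_with_warning(default_population,
                                                        default_relatedness):
    ped, panel = default_population
    coords = dict(panel.coordinates)
    dropped = sorted(coords)[0]
    del coords[dropped]
    with pytest.warns(UserWarning, match=dropped):
        table, _ = camp_pair_analysis(default_relatedness,
                                      panel.memberships, coords)
    n = len(panel.camps()) - 1
    assert len(table) == n * (n - 1) // 2
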