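"""Rank statistics: hand-worked examples, invariance properties, and
cross-checks against scipy's independent implementations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from washtrends import (
    DegenerateSequenceError,
    DomainError,
    kruskal_wallis,
    ks_normal,
    midranks,
    spearman,
    summarize,
)

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


# -- independent oracles ----------------------------------------------------

def rank_by_enumeration(x):
    """Tie-free ranks: 1 + number of strictly smaller values."""
    return [1 + sum(other < xi for other in x) for xi in x]


def pearson(u, v):
    u, v = np.asarray(u, float), np.asarray(v, float)
    du, dv = u - u.mean(), v - v.mean()
    return float((du * dv).sum() / math.sqrt((du * du).sum() * (dv * dv).sum()))


# -- midranks ---------------------------------------------------------------

@pytest.mark.parametrize(
    "values,expected",
    [
        ([10, 20, 30], [1, 2, 3]),
        ([5, 5, 7], [1.5, 1.5, 3]),
        ([0, 0, 0, 0], [2.5, 2.5, 2.5, 2.5]),
        ([3, 1, 4, 1, 5], [3, 1.5, 4, 1.5, 5]),
    ],
)
def test_midranks_examples(values, expected):
    assert midranks(values).tolist() == expected


def test_midranks_empty():
    with pytest.raises(DomainError):
        midranks([])


@given(st.lists(st.integers(-50, 50), min_size=1, max_size=60))
def test_midranks_sum_invariant(values):
    n = len(values)
    assert midranks(values).sum() == pytest.approx(n * (n + 1) / 2)


@given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40))
def test_midranks_matches_scipy(values):
    np.testing.assert_allclose(midranks(values), sps.rankdata(values, method="average"))


# -- Spearman ---------------------------------------------------------------

def test_spearman_identity():
    r = spearman([1, 5, 9, 12], [1, 5, 9, 12])
    assert r.rho == 1 and r.variance_pct == 100 and r.p_two_tailed == 0


def test_spearman_hand_example_with_ties():
    # mid-ranks [1,2,3,4] vs [2.5,2.5,4,1]: product-moment gives -0.31623
    r = spearman([1, 2, 3, 4], [2, 2, 3, 1])
    assert r.rho == pytest.approx(-0.31623, abs=5e-6)


def test_spearman_degenerate_and_short():
    with pytest.raises(DegenerateSequenceError):
        spearman([1, 1, 1], [1, 2, 3])
    with pytest.raises(DomainError):
        spearman([1, 2], [1, 2])
    with pytest.raises(DomainError):
        spearman([1, 2, 3], [1, 2])


@given(
    st.lists(st.integers(0, 10**6), min_size=4, max_size=30, unique=True),
    st.lists(st.integers(0, 10**6), min_size=4, max_size=30, unique=True),
)
def test_spearman_no_ties_d2_formula(x, y):
    """Tie-free mid-rank product-moment rho equals 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    rx, ry = rank_by_enumeration(x), rank_by_enumeration(y)
    d2 = sum((a - b) ** 2 for a, b in zip(rx, ry))
    expected = 1 - 6 * d2 / (n * (n * n - 1))
    assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)


@given(st.permutations(list(range(7))), st.integers(3, 7))
def test_spearman_bruteforce_oracle_small_n(perm, n):
    """For n <= 7 tie-free inputs rho matches the Pearson correlation of
    explicitly enumerated ranks."""
    x = list(range(n))
    y = [perm[i] for i in range(n)]
    expected = pearson(rank_by_enumeration(x), rank_by_enumeration(y))
    assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)


@given(
    st.lists(st.integers(0, 100), min_size=5, max_size=30),
    st.lists(st.integers(0, 100), min_size=5, max_size=30),
)
def test_spearman_symmetry_and_sign(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    try:
        a = spearman(x, y)
    except DegenerateSequenceError:
        return
    assert spearman(y, x).rho == pytest.approx(a.rho, abs=1e-12)
    assert spearman(x, [-v for v in y]).rho == pytest.approx(-a.rho, abs=1e-12)
    assert -1 <= a.rho <= 1 and 0 <= a.p_two_tailed <= 1
    assert a.variance_pct == pytest.approx(100 * a.rho**2)


@given(st.lists(st.integers(0, 1000), min_size=5, max_size=40))
def test_spearman_monotone_transform_invariance(x):
    """Rank-only dependence: strictly increasing transforms leave rho fixed."""
    y = list(range(len(x)))
    try:
        base = spearman(x, y).rho
    except DegenerateSequenceError:
        return
    transformed = [math.exp(v / 100.0) + 3 * v for v in x]  # strictly increasing
    assert spearman(transformed, y).rho == pytest.approx(base, abs=1e-12)


@given(
    st.lists(st.integers(0, 30), min_size=5, max_size=40),
    st.lists(st.integers(0, 30), min_size=5, max_size=40),
)
def test_spearman_rho_matches_scipy_with_ties(x, y):
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    try:
        got = spearman(x, y)
    except DegenerateSequenceError:
        return
    expected = sps.spearmanr(x, y).statistic
    assert got.rho == pytest.approx(expected, abs=1e-10)


def test_spearman_p_value_conventions():
    assert spearman(list(range(17)), list(range(17))).p_two_tailed == 0  # |rho|=1
    r = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    t = r.rho * math.sqrt((r.n - 2) / (1 - r.rho**2))
    assert r.p_two_tailed == pytest.approx(2 * sps.t.sf(abs(t), r.n - 2))


# -- Kruskal-Wallis ---------------------------------------------------------

def test_kruskal_hand_example():
    # no ties: (12/42)*(36/3 + 225/3) - 21 = 3.857
    res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    assert res.statistic == pytest.approx(3.857, abs=5e-4)


def test_kruskal_identical_groups_and_errors():
    res = kruskal_wallis([[1, 1, 1], [1, 1, 1]])
    assert res.statistic == 0 and res.p_value == 1
    with pytest.raises(DomainError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(DomainError):
        kruskal_wallis([[1], []])


@given(
    st.lists(
        st.lists(st.integers(0, 20), min_size=2, max_size=15),
        min_size=2,
        max_size=4,
    )
)
def test_kruskal_matches_scipy_and_nonnegative(groups):
    res = kruskal_wallis(groups)
    assert res.statistic >= 0
    pooled = [v for g in groups for v in g]
    if len(set(pooled)) > 1:
        expected = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(expected.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(expected.pvalue, abs=1e-10)


@given(st.lists(st.integers(0, 100), min_size=6, max_size=30))
def test_kruskal_monotone_invariance(pooled):
    """H is a rank statistic: strictly increasing transforms leave it fixed."""
    half = len(pooled) // 2
    groups = [pooled[:half], pooled[half:]]
    base = kruskal_wallis(groups).statistic
    transformed = [[v * 3 + 7 for v in g] for g in groups]
    assert kruskal_wallis(transformed).statistic == pytest.approx(base, abs=1e-12)


# -- K-S normality screen ---------------------------------------------------

def test_ks_hand_example():
    # sample [-1, 0, 1]: mean 0, sample std 1; sup distance is 1/3 - Phi(-1)
    res = ks_normal([-1.0, 0.0, 1.0])
    expected = 1.0 / 3.0 - sps.norm.cdf(-1.0)  # = 0.1746781...
    assert res.statistic == pytest.approx(expected, abs=1e-9)
    assert res.statistic == pytest.approx(0.1746, abs=1e-4)


def test_ks_fitted_quantile_construction():
    # sample at the fitted normal's (i-0.5)/n quantiles -> D near 0.5/n
    n = 500
    q = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    res = ks_normal(q)
    assert res.statistic == pytest.approx(0.5 / n, rel=0.15)


def test_ks_constant_sample():
    with pytest.raises(DomainError):
        ks_normal([4.0, 4.0, 4.0])


def test_ks_statistic_matches_scipy_fitted():
    rng = np.random.default_rng(7)
    x = rng.normal(10, 3, size=80)
    res = ks_normal(x)
    d_scipy = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic
    assert res.statistic == pytest.approx(d_scipy, abs=1e-12)
    # asymptotic Kolmogorov p at sqrt(n)*D, no small-sample correction
    assert res.p_value == pytest.approx(sps.kstwobign.sf(math.sqrt(80) * res.statistic))


def test_ks_verdict_threshold():
    rng = np.random.default_rng(3)
    assert "not" in ks_normal(rng.normal(size=60)).verdict
    assert "not" not in ks_normal(rng.exponential(size=200)).verdict


# -- summary stats ----------------------------------------------------------

def test_summarize_examples():
    s = summarize([5, 5, 5])
    assert (s.mean, s.std, s.median, s.mode) == (5, 0, 5, 5)
    s = summarize([1, 2, 2, 9])
    assert s.mean == 3.5 and s.median == 2 and s.mode == 2
    assert s.std == pytest.approx(math.sqrt(41 / 3), abs=5e-4)
    with pytest.raises(DomainError):
        summarize([])


def test_summarize_mode_first_encounter_tiebreak():
    assert summarize([7, 3, 3, 7]).mode == 7
    assert summarize([3, 7, 7, 3]).mode == 3


@given(st.lists(st.integers(-100, 100), min_size=2, max_size=50))
def test_summarize_matches_numpy(values):
    s = summarize(values)
    arr = np.asarray(values, float)
    assert s.mean == pytest.approx(arr.mean())
    assert s.std == pytest.approx(arr.std(ddof=1))
    assert s.median == pytest.approx(np.median(arr))
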