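"""Unit and property tests for the national loglinear index engine."""

import numpy as np
import pytest
import scipy.optimize

from avitrend import (
    CountMatrix,
    aggregate_visits,
    compute_indices,
    compute_time_totals,
    fit_loglinear,
    fit_stratified,
    impute_missing,
)
from avitrend.trim import FitError

from conftest import random_count_matrix


# ---------------------------------------------------------------------------
# visit aggregation


@pytest.mark.parametrize(
    "visits, rule, expected",
    [
        ([2, 4], "mean", 3.0),
        ([2, 4], "max", 4.0),
        ([2, 4], "second_visit", 4.0),
        ([1, 2, 6], "mean", 3.0),
        ([0, 0], "max", 0.0),
    ],
)
def test_aggregate_visits(visits, rule, expected):
    assert aggregate_visits(visits, rule) == expected


def test_aggregate_visits_errors():
    with pytest.raises(ValueError, match="at least two"):
        aggregate_visits([5], "second_visit")
    with pytest.raises(ValueError, match="unknown aggregation rule"):
        aggregate_visits([1, 2], "median")


# ---------------------------------------------------------------------------
# fitting: closed forms and the numeric likelihood oracle


def _oracle_fit(cm: CountMatrix):
    """Brute-force numeric maximisation of the observed-cell Poisson likelihood.

    Independent of the iterative fitter: parameterises (log a, log g_{j>0})
    and hands the exact negative log-likelihood and gradient to BFGS.
    """
    f, mask = cm.counts, cm.mask
    S, J = f.shape

    def unpack(theta):
        a = np.exp(theta[:S])
        g = np.concatenate([[1.0], np.exp(theta[S:])])
        return a, g

    def nll(theta):
        a, g = unpack(theta)
        mu = np.outer(a, g)
        return -np.sum(mask * (f * np.log(mu) - mu))

    def grad(theta):
        a, g = unpack(theta)
        mu = np.outer(a, g)
        d = mask * (f - mu)  # d nll / d log-param = -(f - mu) summed over matches
        return -np.concatenate([d.sum(axis=1), d.sum(axis=0)[1:]])

    x0 = np.zeros(S + J - 1)
    res = scipy.optimize.minimize(nll, x0, jac=grad, method="BFGS", tol=1e-14)
    return unpack(res.x)


def test_complete_2x2_closed_form(complete_2x2):
    fit = fit_loglinear(complete_2x2)
    np.testing.assert_allclose(fit.year_effects, [1.0, 2.0], rtol=1e-10)
    totals = compute_time_totals(impute_missing(fit, complete_2x2))
    series = compute_indices(fit, totals, 2000, complete_2x2.years)
    np.testing.assert_allclose(series.index, [1.0, 2.0], rtol=1e-12)


def test_constant_counts_give_flat_index():
    cm = CountMatrix(
        counts=np.full((4, 6), 7.0), mask=np.ones((4, 6), bool), years=np.arange(6)
    )
    fit = fit_loglinear(cm)
    np.testing.assert_allclose(fit.year_effects, 1.0, rtol=1e-10)
    totals = compute_time_totals(impute_missing(fit, cm))
    series = compute_indices(fit, totals, 0, cm.years)
    np.testing.assert_allclose(series.index, 1.0, rtol=1e-12)


def test_three_cell_exact_solution(three_cell):
    """With 3 observed cells and 3 free parameters the ML fit interpolates."""
    fit = fit_loglinear(three_cell)
    np.testing.assert_allclose(fit.site_effects, [10.0, 30.0], rtol=1e-8)
    np.testing.assert_allclose(fit.year_effects, [1.0, 2.0], rtol=1e-8)
    assert fit.mu[1, 1] == pytest.approx(60.0, rel=1e-8)
    completed = impute_missing(fit, three_cell)
    np.testing.assert_allclose(
        completed.counts, [[10.0, 20.0], [30.0, 60.0]], rtol=1e-8
    )
    np.testing.assert_allclose(
        compute_time_totals(completed), [40.0, 80.0], rtol=1e-8
    )


@pytest.mark.parametrize("seed", range(8))
def test_oracle_equivalence_random_instances(seed):
    """IPF solution matches direct numeric likelihood maximisation (<=6x5)."""
    rng = np.random.default_rng(100 + seed)
    n_sites = int(rng.integers(3, 7))
    n_years = int(rng.integers(3, 6))
    cm = random_count_matrix(rng, n_sites, n_years, missing_rate=0.3)
    fit = fit_loglinear(cm)
    a_star, g_star = _oracle_fit(cm)
    np.testing.assert_allclose(fit.year_effects, g_star, rtol=1e-6)
    np.testing.assert_allclose(fit.site_effects, a_star, rtol=1e-6)


def test_scale_invariance_of_year_effects():
    """Rescaling one site (a detectability change) is absorbed by its site effect.

    On rank-1 data this leaves the year effects exactly unchanged; with
    sampling noise the fitted year effects are column-total ratios and the
    property only holds approximately, so the exact check uses noise-free
    counts.
    """
    rng = np.random.default_rng(5)
    a = rng.lognormal(2.5, 0.5, 5)
    g = np.array([1.0, 1.2, 0.9, 1.4])
    counts = np.outer(a, g)
    cm = CountMatrix(counts=counts, mask=np.ones((5, 4), bool), years=np.arange(4))
    fit = fit_loglinear(cm)
    scaled = CountMatrix(
        counts=counts * np.array([3.0, 1, 1, 1, 1])[:, None],
        mask=cm.mask,
        years=cm.years,
    )
    fit2 = fit_loglinear(scaled)
    np.testing.assert_allclose(fit.year_effects, fit2.year_effects, rtol=1e-9)
    assert fit2.site_effects[0] == pytest.approx(3 * fit.site_effects[0], rel=1e-9)


def test_loglik_trace_monotone():
    rng = np.random.default_rng(17)
    cm = random_count_matrix(rng, 6, 5, missing_rate=0.3)
    fit = fit_loglinear(cm)
    assert fit.converged
    diffs = np.diff(fit.loglik_trace)
    assert np.all(diffs >= -1e-9 * np.abs(fit.loglik_trace[:-1]))


def test_disconnected_years_rejected():
    # sites 1 and 2 never share a year with sites 3 and 4
    mask = np.array(
        [
            [True, True, False, False],
            [True, True, False, False],
            [False, False, True, True],
            [False, False, True, True],
        ]
    )
    cm = CountMatrix(
        counts=np.full((4, 4), 5.0), mask=mask, years=np.array([1990, 1991, 1992, 1993])
    )
    with pytest.raises(FitError, match="1992.*1993|unreachable"):
        fit_loglinear(cm)


def test_all_zero_site_does_not_crash():
    counts = np.array([[5.0, 10.0], [0.0, 0.0]])
    cm = CountMatrix(counts=counts, mask=np.ones((2, 2), bool), years=[0, 1])
    fit = fit_loglinear(cm)
    assert np.isfinite(fit.loglik)
    totals = compute_time_totals(impute_missing(fit, cm))
    np.testing.assert_allclose(totals, [5.0, 10.0], atol=1e-6)


# ---------------------------------------------------------------------------
# stratified fitting


def test_single_stratum_equals_pooled():
    rng = np.random.default_rng(23)
    cm = random_count_matrix(rng, 5, 4, missing_rate=0.2)
    pooled = fit_loglinear(cm)
    strat = fit_stratified(cm)
    np.testing.assert_allclose(pooled.year_effects, strat.year_effects)


def test_stratified_imputation_uses_only_same_stratum():
    """Strata with different true year effects impute differently than pooled."""
    rng = np.random.default_rng(31)
    years = np.arange(2000, 2006)
    a = rng.lognormal(3, 0.2, 8)
    g_up = 1.10 ** np.arange(6)
    g_down = 0.90 ** np.arange(6)
    counts = np.vstack(
        [np.outer(a[:4], g_up), np.outer(a[4:], g_down)]
    )
    f = rng.poisson(counts * 4).astype(float)
    mask = np.ones_like(f, bool)
    mask[0, 5] = False  # one missing cell in the increasing stratum
    strata = np.array(["up"] * 4 + ["down"] * 4, dtype=object)
    cm = CountMatrix(counts=f, mask=mask, years=years, strata=strata)

    strat_fit = fit_stratified(cm)
    pooled_fit = fit_loglinear(cm)
    # per-stratum oracle: fitting the increasing stratum alone gives the
    # imputed value the stratified fit must reproduce
    up_only = CountMatrix(counts=f[:4], mask=mask[:4], years=years)
    oracle = fit_loglinear(up_only)
    assert strat_fit.mu[0, 5] == pytest.approx(oracle.mu[0, 5], rel=1e-8)
    assert strat_fit.mu[0, 5] != pytest.approx(pooled_fit.mu[0, 5], rel=0.05)


def test_stratified_permutation_invariance():
    rng = np.random.default_rng(41)
    cm = random_count_matrix(rng, 6, 4, missing_rate=0.2)
    cm.strata[:] = ["a", "b", "a", "b", "a", "b"]
    fit = fit_stratified(cm)
    perm = rng.permutation(6)
    cm2 = CountMatrix(
        counts=cm.counts[perm],
        mask=cm.mask[perm],
        years=cm.years,
        sites=cm.sites[perm],
        strata=cm.strata[perm],
        weights=cm.weights[perm],
    )
    fit2 = fit_stratified(cm2)
    np.testing.assert_allclose(fit.year_effects, fit2.year_effects, rtol=1e-9)


def test_stratified_empty_year_in_stratum_rejected():
    mask = np.array([[True, False], [True, True]])
    cm = CountMatrix(
        counts=np.array([[4.0, 0.0], [5.0, 6.0]]),
        mask=mask,
        years=[2000, 2001],
        strata=np.array(["a", "b"], dtype=object),
    )
    with pytest.raises(FitError, match="stratum 'a'"):
        fit_stratified(cm)


# ---------------------------------------------------------------------------
# totals, indices, uncertainty


def test_time_totals_and_weights(complete_2x2):
    fit = fit_loglinear(complete_2x2)
    completed = impute_missing(fit, complete_2x2)
    np.testing.assert_allclose(compute_time_totals(completed), [40.0, 80.0])
    doubled = CountMatrix(
        counts=completed.counts,
        mask=completed.mask,
        years=completed.years,
        weights=np.array([2.0, 1.0]),
    )
    np.testing.assert_allclose(compute_time_totals(doubled), [50.0, 100.0])


def test_time_totals_rejects_missing(three_cell):
    with pytest.raises(ValueError, match="missing"):
        compute_time_totals(three_cell)


def test_impute_dimension_mismatch(complete_2x2, three_cell):
    fit = fit_loglinear(complete_2x2)
    bad = CountMatrix(
        counts=np.ones((3, 2)), mask=np.ones((3, 2), bool), years=[2000, 2001]
    )
    with pytest.raises(ValueError, match="dimensions"):
        impute_missing(fit, bad)


def test_index_base_year_anchoring(complete_2x2):
    fit = fit_loglinear(complete_2x2)
    totals = compute_time_totals(impute_missing(fit, complete_2x2))
    series = compute_indices(fit, totals, 2000, complete_2x2.years)
    assert series.index[0] == 1.0
    assert series.se[0] == 0.0
    assert np.allclose(series.cov, series.cov.T)
    assert np.all(np.linalg.eigvalsh(series.cov) > -1e-12)
    with pytest.raises(ValueError, match="base year"):
        compute_indices(fit, totals, 1999, complete_2x2.years)
    with pytest.raises(ValueError, match="zero"):
        compute_indices(fit, np.array([0.0, 80.0]), 2000, complete_2x2.years)


def test_index_se_matches_parametric_bootstrap():
    """Delta-method SEs agree with a 2000-resample parametric bootstrap."""
    rng = np.random.default_rng(11)
    S, J = 20, 5
    years = np.arange(J)
    a = rng.lognormal(3.0, 0.5, S)
    g = 1.03 ** np.arange(J)
    f = rng.poisson(np.outer(a, g)).astype(float)
    cm = CountMatrix(counts=f, mask=np.ones((S, J), bool), years=years)
    fit = fit_loglinear(cm, overdispersion=False)
    series = compute_indices(
        fit, compute_time_totals(impute_missing(fit, cm)), 0, years
    )
    boot = []
    for _ in range(2000):
        fb = rng.poisson(fit.mu).astype(float)
        cmb = CountMatrix(counts=fb, mask=cm.mask, years=years)
        fitb = fit_loglinear(cmb, overdispersion=False)
        totb = compute_time_totals(impute_missing(fitb, cmb))
        boot.append(totb / totb[0])
    boot_se = np.std(np.asarray(boot), axis=0, ddof=1)
    np.testing.assert_allclose(series.se[1:], boot_se[1:], rtol=0.15)
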