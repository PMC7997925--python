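"""National species indices from site-by-year count matrices.

The model behind national breeding-bird indices is a loglinear (rank-1
multiplicative) Poisson model: the expected count of a species at site *i*
in year *j* is

    mu_ij = a_i * g_j

where ``a_i`` is a site effect (average abundance at the plot) and ``g_j``
a year effect carrying the population signal.  The year effect at the base
(reference) year is fixed to 1, so the fitted year effects are directly
interpretable as indices relative to the reference year.  Missing
site-by-year cells — skipped visits, abandoned plots, multi-year rotation —
are imputed with their fitted expectations, under the assumption that
populations on non-counted plots change like those on counted plots
(optionally restricted to plots of the same stratum).

Fitting is by iterative proportional fitting restricted to observed cells,
which is coordinate ascent on the Poisson log-likelihood and therefore
monotone.  Standard errors come from the inverse observed-cell Fisher
information of the log-scale parameters, optionally inflated by an
overdispersion factor estimated from Pearson residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountMatrix",
    "LoglinearFit",
    "NationalIndexSeries",
    "aggregate_visits",
    "fit_loglinear",
    "fit_stratified",
    "impute_missing",
    "compute_time_totals",
    "compute_indices",
]

#: relative log-likelihood change below which the fit is declared converged
TOLERANCE = 1e-8
#: additional stability requirement on the year effects between iterations;
#: the likelihood is nearly flat close to an exact-fit optimum, so the
#: log-likelihood criterion alone can stop with parameters still ~1e-3 off
PARAM_TOLERANCE = 1e-12
MAX_ITER = 10_000

#: floor for site effects when evaluating mu (sites observed but always zero)
SITE_EFFECT_FLOOR = 1e-12


class FitError(ValueError):
    """Raised when a count matrix cannot be fitted (e.g. disconnected years)."""


@dataclass
class CountMatrix:
    """Site-by-year counts for one species in one national scheme.

    Parameters
    ----------
    counts
        ``(n_sites, n_years)`` array of non-negative counts.  Entries at
        masked-out cells are ignored (may be NaN).
    mask
        Boolean array, same shape; ``True`` marks an observed cell.
    years
        Calendar year for each column.
    sites
        Site labels; defaults to ``0..n_sites-1``.
    strata
        Stratum label per site (sites with similar environmental
        characteristics, used for stratified imputation).  Defaults to a
        single stratum.
    weights
        Positive site weight per site (post-hoc stratification weighting);
        defaults to 1.
    """

    counts: np.ndarray
    mask: np.ndarray
    years: np.ndarray
    sites: np.ndarray | None = None
    strata: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.years = np.asarray(self.years, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d site-by-year array")
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape must equal counts shape")
        n_sites, n_years = self.counts.shape
        if len(self.years) != n_years:
            raise ValueError("years length must equal number of columns")
        if self.sites is None:
            self.sites = np.arange(n_sites)
        else:
            self.sites = np.asarray(self.sites)
        if self.strata is None:
            self.strata = np.zeros(n_sites, dtype=object)
            self.strata[:] = "all"
        else:
            self.strata = np.asarray(self.strata, dtype=object)
        if self.weights is None:
            self.weights = np.ones(n_sites)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("site weights must be positive")
        observed = self.counts[self.mask]
        if np.any(~np.isfinite(observed)) or np.any(observed < 0):
            raise ValueError("observed counts must be finite and non-negative")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_years(self) -> int:
        return self.counts.shape[1]


@dataclass
class LoglinearFit:
    """Result of a rank-1 Poisson fit: effects, fitted values, uncertainty."""

    site_effects: np.ndarray
    year_effects: np.ndarray  # g, with g[base_col] == 1
    base_col: int
    mu: np.ndarray  # fitted a_i * g_j for every cell
    loglik_trace: np.ndarray
    converged: bool
    covlog_g: np.ndarray  # covariance of log year effects; base row/col zero
    sigma_sq: float  # overdispersion (variance inflation) factor applied
    stratum_fits: dict | None = None  # stratum -> (LoglinearFit, site index array)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class NationalIndexSeries:
    """Per-year national index relative to the base year, with uncertainty.

    ``index`` is on the internal scale (1.0 at the base year); writers may
    rescale to 100 for presentation.  ``cov`` is the delta-method covariance
    of the index values (zero row/column at the base year).  ``totals`` are
    the imputed time totals T_j, the quantity exchanged with the
    supranational combination stage.
    """

    years: np.ndarray
    index: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    base_year: int
    totals: np.ndarray
    country: str = ""
    species: str = ""
    euring_code: int = 0

    def __post_init__(self) -> None:
        b = int(np.flatnonzero(self.years == self.base_year)[0])
        assert abs(self.index[b] - 1.0) < 1e-12
        assert self.se[b] == 0.0

    @property
    def base_col(self) -> int:
        return int(np.flatnonzero(self.years == self.base_year)[0])

    def covlog(self) -> np.ndarray:
        """Covariance of log index values (delta method inverse)."""
        out = np.zeros_like(self.cov)
        nz = self.index > 0
        scale = np.where(nz, self.index, 1.0)
        out = self.cov / np.outer(scale, scale)
        return out


# ---------------------------------------------------------------------------
# visit aggregation


def aggregate_visits(visit_counts, rule: str):
    """Collapse within-season visit counts at one site-year into one count.

    ``mean`` keeps fractional means (the model works on expectations, so no
    rounding is applied); ``max`` takes the visit maximum; ``second_visit``
    uses only the second visit, the convention for species whose first visit
    falls in the migration period.
    """
    visits = np.asarray(visit_counts, dtype=float)
    if visits.ndim != 1 or visits.size == 0:
        raise ValueError("visit_counts must be a non-empty 1-d sequence")
    if rule == "mean":
        return float(visits.mean())
    if rule == "max":
        return float(visits.max())
    if rule == "second_visit":
        if visits.size < 2:
            raise ValueError("second_visit rule requires at least two visits")
        return float(visits[1])
    raise ValueError(f"unknown aggregation rule: {rule!r}")


# ---------------------------------------------------------------------------
# fitting


def _check_connected(mask: np.ndarray, years: np.ndarray, base_col: int) -> None:
    """Every year must be linked to the base year through shared sites."""
    n_years = mask.shape[1]
    empty = np.flatnonzero(mask.sum(axis=0) == 0)
    if empty.size:
        raise FitError(
            "years with no observed sites: " + ", ".join(str(years[j]) for j in empty)
        )
    # union-find over year columns; a site observed in several years links them
    parent = list(range(n_years))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row in mask:
        cols = np.flatnonzero(row)
        for j in cols[1:]:
            ra, rb = find(int(cols[0])), find(int(j))
            if ra != rb:
                parent[ra] = rb
    root = find(base_col)
    unreachable = [years[j] for j in range(n_years) if find(j) != root]
    if unreachable:
        raise FitError(
            "year graph disconnected; unreachable years: "
            + ", ".join(map(str, unreachable))
        )


def _poisson_loglik(f: np.ndarray, mu: np.ndarray, mask: np.ndarray) -> float:
    mu_obs = mu[mask]
    f_obs = f[mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f_obs > 0, f_obs * np.log(np.maximum(mu_obs, 1e-300)), 0.0)
    return float(np.sum(term - mu_obs))


def _fisher_covlog_g(
    a: np.ndarray, g: np.ndarray, mask: np.ndarray, base_col: int
) -> np.ndarray:
    """Covariance of log year effects from the observed-cell Fisher information.

    Parameters are (log a_i, log g_j for j != base); with a log link the
    information contribution of one observed cell is mu_ij on each matching
    diagonal entry and cross term.  Sites with a zero (floored) effect carry
    no information about g and are dropped from the matrix.
    """
    active = a > SITE_EFFECT_FLOOR * 10
    if not np.any(active):
        return np.zeros((len(g), len(g)))
    mu = np.outer(a[active], g) * mask[active]
    n_s = int(active.sum())
    cols = [j for j in range(len(g)) if j != base_col]
    n = n_s + len(cols)
    F = np.zeros((n, n))
    F[:n_s, :n_s] = np.diag(mu.sum(axis=1))
    F[n_s:, n_s:] = np.diag(mu.sum(axis=0)[cols])
    F[:n_s, n_s:] = mu[:, cols]
    F[n_s:, :n_s] = mu[:, cols].T
    try:
        cov = np.linalg.inv(F)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(F)
    covg = np.zeros((len(g), len(g)))
    sub = cov[n_s:, n_s:]
    for x, j in enumerate(cols):
        for y, k in enumerate(cols):
            covg[j, k] = sub[x, y]
    return covg


def fit_loglinear(
    counts: CountMatrix,
    base_year: int | None = None,
    *,
    tol: float = TOLERANCE,
    max_iter: int = MAX_ITER,
    overdispersion: bool = True,
) -> LoglinearFit:
    """Maximum-likelihood fit of ``mu_ij = a_i * g_j`` over observed cells.

    Alternating multiplicative updates (iterative proportional fitting on the
    observed cells) maximise the Poisson likelihood; each half-step solves
    the score equation for one block exactly, so the log-likelihood trace is
    non-decreasing.  ``g`` is identified by fixing it to 1 at the base year.

    With ``overdispersion=True`` (default) a variance-inflation factor is
    estimated from Pearson residuals and all covariances are scaled by it
    (floored at 1, i.e. underdispersion never shrinks the errors).
    """
    f, mask, years = counts.counts, counts.mask, counts.years
    if base_year is None:
        base_year = int(years[0])
    base_candidates = np.flatnonzero(years == base_year)
    if base_candidates.size == 0:
        raise FitError(f"base year {base_year} not in series {years[0]}–{years[-1]}")
    base_col = int(base_candidates[0])
    _check_connected(mask, years, base_col)

    row_obs = mask.sum(axis=1)
    if np.any(row_obs == 0):
        raise FitError("sites with no observed cells cannot be fitted; drop them first")

    fm = np.where(mask, f, 0.0)
    row_tot = fm.sum(axis=1)
    a = row_tot / np.maximum(row_obs, 1)
    a = np.maximum(a, SITE_EFFECT_FLOOR)
    g = np.ones(counts.n_years)

    trace = [_poisson_loglik(f, np.outer(a, g), mask)]
    converged = False
    g_prev = g.copy()
    for _ in range(max_iter):
        # exact block maximisers given the other block
        denom_a = (mask * g).sum(axis=1)
        a = row_tot / denom_a
        a = np.maximum(a, SITE_EFFECT_FLOOR)
        denom_g = (mask * a[:, None]).sum(axis=0)
        g = fm.sum(axis=0) / denom_g
        g = np.maximum(g, SITE_EFFECT_FLOOR)
        # renormalise so the base-year effect is exactly 1
        scale = g[base_col]
        g = g / scale
        a = a * scale
        ll = _poisson_loglik(f, np.outer(a, g), mask)
        trace.append(ll)
        param_drift = float(np.max(np.abs(g / np.maximum(g_prev, 1e-300) - 1.0)))
        if (
            abs(ll - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12)
            and param_drift <= PARAM_TOLERANCE
        ):
            converged = True
            break
        g_prev = g.copy()

    mu = np.outer(np.maximum(a, SITE_EFFECT_FLOOR), g)

    sigma_sq = 1.0
    if overdispersion:
        mu_obs = mu[mask]
        f_obs = f[mask]
        ok = mu_obs > SITE_EFFECT_FLOOR * 10
        n_par = int(np.sum(a > SITE_EFFECT_FLOOR * 10)) + counts.n_years - 1
        dof = int(ok.sum()) - n_par
        if dof > 0:
            pearson = np.sum((f_obs[ok] - mu_obs[ok]) ** 2 / mu_obs[ok])
            sigma_sq = max(1.0, float(pearson / dof))

    covg = _fisher_covlog_g(a, g, mask, base_col) * sigma_sq

    return LoglinearFit(
        site_effects=a,
        year_effects=g,
        base_col=base_col,
        mu=mu,
        loglik_trace=np.asarray(trace),
        converged=converged,
        covlog_g=covg,
        sigma_sq=sigma_sq,
    )


def fit_stratified(
    counts: CountMatrix, base_year: int | None = None, **kwargs
) -> LoglinearFit:
    """Independent per-stratum fits; imputation only borrows same-stratum sites.

    Stratum results are assembled back into full-scheme matrices.  The
    combined log-total covariance (used downstream for index errors) sums
    stratum contributions on the weighted-total scale, treating strata as
    independent.
    """
    strata = counts.strata
    labels = list(dict.fromkeys(strata))  # stable order of appearance
    if len(labels) == 1:
        return fit_loglinear(counts, base_year, **kwargs)
    if base_year is None:
        base_year = int(counts.years[0])
    base_col = int(np.flatnonzero(counts.years == base_year)[0])

    mu = np.zeros_like(counts.counts, dtype=float)
    a_all = np.zeros(counts.n_sites)
    sub_fits: dict = {}
    totals = np.zeros(counts.n_years)
    cov_tot = np.zeros((counts.n_years, counts.n_years))
    trace_len = 0
    converged = True
    sigma_sq = 0.0
    for lab in labels:
        rows = np.flatnonzero(strata == lab)
        sub = CountMatrix(
            counts=counts.counts[rows],
            mask=counts.mask[rows],
            years=counts.years,
            sites=counts.sites[rows],
            weights=counts.weights[rows],
        )
        try:
            fit = fit_loglinear(sub, base_year, **kwargs)
        except FitError as err:
            raise FitError(f"stratum {lab!r}: {err}") from err
        sub_fits[lab] = (fit, rows)
        mu[rows] = fit.mu
        a_all[rows] = fit.site_effects
        w = counts.weights[rows][:, None]
        completed = np.where(sub.mask, sub.counts, fit.mu)
        t_s = (w * completed).sum(axis=0)
        totals += t_s
        cov_tot += np.outer(t_s, t_s) * fit.covlog_g
        trace_len = max(trace_len, len(fit.loglik_trace))
        converged = converged and fit.converged
        sigma_sq = max(sigma_sq, fit.sigma_sq)

    # pooled year effects for reporting: ratio of fitted totals
    g_pool = totals / totals[base_col]
    covg = cov_tot / np.outer(totals, totals)
    covg[base_col, :] = 0.0
    covg[:, base_col] = 0.0

    trace = np.array([sum(f.loglik_trace[-1] for f, _ in sub_fits.values())])
    return LoglinearFit(
        site_effects=a_all,
        year_effects=g_pool,
        base_col=base_col,
        mu=mu,
        loglik_trace=trace,
        converged=converged,
        covlog_g=covg,
        sigma_sq=sigma_sq,
        stratum_fits=sub_fits,
    )


def impute_missing(fit: LoglinearFit, counts: CountMatrix) -> CountMatrix:
    """Replace missing cells with fitted expectations; observed cells unchanged."""
    if fit.mu.shape != counts.counts.shape:
        raise ValueError("fit and counts dimensions do not match")
    completed = np.where(counts.mask, counts.counts, fit.mu)
    return CountMatrix(
        counts=completed,
        mask=np.ones_like(counts.mask, dtype=bool),
        years=counts.years,
        sites=counts.sites,
        strata=counts.strata,
        weights=counts.weights,
    )


def compute_time_totals(completed: CountMatrix) -> np.ndarray:
    """Weighted yearly totals T_j over all plots of the completed matrix."""
    if not completed.mask.all():
        raise ValueError("completed matrix still has missing cells")
    return (completed.weights[:, None] * completed.counts).sum(axis=0)


def compute_indices(
    fit: LoglinearFit,
    totals: np.ndarray,
    base_year: int,
    years: np.ndarray,
    *,
    country: str = "",
    species: str = "",
    euring_code: int = 0,
) -> NationalIndexSeries:
    """Indices I_j = T_j / T_base with delta-method standard errors.

    The index uncertainty is driven by the year-effect uncertainty of the
    fit: Var(I_j) ≈ I_j² Var(log g_j), with the full covariance carried along
    for trend fitting downstream.
    """
    years = np.asarray(years, dtype=int)
    b = np.flatnonzero(years == base_year)
    if b.size == 0:
        raise ValueError(f"base year {base_year} not within the series")
    b = int(b[0])
    if totals[b] <= 0:
        raise ValueError("base-year time total is zero; cannot form indices")
    index = totals / totals[b]
    cov = np.outer(index, index) * fit.covlog_g
    cov[b, :] = 0.0
    cov[:, b] = 0.0
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return NationalIndexSeries(
        years=years,
        index=index,
        se=se,
        cov=cov,
        base_year=int(base_year),
        totals=np.asarray(totals, dtype=float),
        country=country,
        species=species,
        euring_code=euring_code,
    )
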