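"""Combine national index series into supranational (European) indices.

The continental combination mirrors the national stage but operates on
national model output (imputed yearly time totals, standard errors and
covariance matrices) instead of raw plot counts.  Three ingredients:

* **Population weighting** — each country's totals are rescaled so that its
  level matches its breeding-population estimate (pairs) over a recent
  reference window.  A country's contribution is then proportional to its
  population, not to how many plots its scheme happens to survey.
* **Regional imputation** — schemes started in different years; a country's
  pre-scheme years are back-cast by chaining the between-year ratios of a
  regional composite built from same-region countries that do have data.
* **Summation** — the continental total per year is the sum of scaled
  national totals; the index is the total relative to the base year, with
  variances propagated assuming independence between national schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NationalSubmission",
    "EuropeanIndexSeries",
    "compute_weights",
    "impute_national",
    "combine",
    "combine_national",
]


class CombineError(ValueError):
    pass


@dataclass
class NationalSubmission:
    """One country's contribution for one species on a common year grid.

    ``totals`` holds imputed yearly time totals; NaN marks years before the
    scheme start (to be filled by regional imputation).  ``covlog`` is the
    covariance of log totals relative to the national base year (zero
    row/column there).
    """

    country: str
    species: str
    euring_code: int
    years: np.ndarray
    totals: np.ndarray
    covlog: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.totals = np.asarray(self.totals, dtype=float)
        self.covlog = np.asarray(self.covlog, dtype=float)
        present = self.totals[~np.isnan(self.totals)]
        if np.any(present <= 0):
            raise ValueError("time totals must be positive where present")
        if self.covlog.shape != (len(self.years), len(self.years)):
            raise ValueError("covlog shape must match the year grid")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.totals)

    @property
    def first_year(self) -> int:
        return int(self.years[self.observed][0])

    @property
    def se(self) -> np.ndarray:
        """Standard error of totals (delta method from log-scale variance)."""
        var = np.diag(self.covlog)
        return np.where(self.observed, self.totals * np.sqrt(np.maximum(var, 0)), np.nan)


@dataclass
class EuropeanIndexSeries:
    """Combined supranational index with uncertainty and provenance."""

    species: str
    euring_code: int
    base_year: int
    years: np.ndarray
    index: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    contributing: list[list[str]] = field(default_factory=list)  # per-year countries

    def covlog(self) -> np.ndarray:
        scale = np.where(self.index > 0, self.index, 1.0)
        return self.cov / np.outer(scale, scale)


def _weight_of(weights: pd.DataFrame, country: str, species: str) -> float:
    row = weights[(weights.country == country) & (weights.species == species)]
    if row.empty:
        raise CombineError(f"no population weight for {country}/{species}")
    return float(row["pairs"].iloc[0])


def compute_weights(
    submissions: list[NationalSubmission],
    weights: pd.DataFrame,
    reference_window: tuple[int, int],
) -> list[NationalSubmission]:
    """Rescale each country's totals to its breeding-population estimate.

    The scale factor is N_cs divided by the mean observed total over the
    reference window, so the country's level over that window equals its
    population size.  Log-scale covariances are unaffected by rescaling.
    """
    lo, hi = reference_window
    out = []
    for sub in submissions:
        n_pairs = _weight_of(weights, sub.country, sub.species)
        inside = (sub.years >= lo) & (sub.years <= hi) & sub.observed
        if not inside.any():
            raise CombineError(
                f"reference window {lo}–{hi} has no observed totals for "
                f"{sub.country}/{sub.species}"
            )
        scale = n_pairs / float(sub.totals[inside].mean())
        out.append(replace(sub, totals=sub.totals * scale, covlog=sub.covlog.copy()))
    return out


def _ratio_logvar(donors: list[NationalSubmission], j: int) -> float:
    """Log-variance of the composite between-year ratio total_j / total_{j+1}."""
    s0 = sum(d.totals[j] for d in donors)
    s1 = sum(d.totals[j + 1] for d in donors)
    v0 = sum(d.totals[j] ** 2 * d.covlog[j, j] for d in donors)
    v1 = sum(d.totals[j + 1] ** 2 * d.covlog[j + 1, j + 1] for d in donors)
    c01 = sum(d.totals[j] * d.totals[j + 1] * d.covlog[j, j + 1] for d in donors)
    return max(v0 / s0**2 + v1 / s1**2 - 2 * c01 / (s0 * s1), 0.0)


def impute_national(
    submissions: list[NationalSubmission],
    region_assignment: dict[str, str],
) -> list[NationalSubmission]:
    """Back-cast pre-scheme years from same-region donors.

    For each missing year (necessarily before the scheme start), the
    country's total changes year-over-year by exactly the regional
    composite's ratio, computed from the donor countries observed in both
    adjacent years.  Uncertainty of the chained ratios is accumulated on the
    log scale treating successive ratios as independent — a documented
    simplification.
    """
    for sub in submissions:
        if sub.country not in region_assignment:
            raise CombineError(f"country {sub.country!r} has no region assigned")
    out = []
    for sub in submissions:
        if sub.observed.all():
            out.append(sub)
            continue
        region = region_assignment[sub.country]
        donors_all = [
            d
            for d in submissions
            if d is not sub
            and d.species == sub.species
            and region_assignment[d.country] == region
        ]
        totals = sub.totals.copy()
        covlog = sub.covlog.copy()
        first = int(np.flatnonzero(sub.observed)[0])
        chain_var = 0.0
        for j in range(first - 1, -1, -1):
            donors = [d for d in donors_all if d.observed[j] and d.observed[j + 1]]
            if not donors:
                raise CombineError(
                    f"region {region!r} has no donor coverage for "
                    f"{sub.species} in year {sub.years[j]}"
                )
            ratio = sum(d.totals[j] for d in donors) / sum(
                d.totals[j + 1] for d in donors
            )
            totals[j] = totals[j + 1] * ratio
            chain_var += _ratio_logvar(donors, j)
            covlog[j, :] = covlog[first, :]
            covlog[:, j] = covlog[:, first]
            covlog[j, j] = covlog[first, first] + chain_var
        out.append(replace(sub, totals=totals, covlog=covlog))
    return out


def combine(
    completed: list[NationalSubmission],
    base_year: int | None = None,
) -> EuropeanIndexSeries:
    """Sum scaled national totals and express them relative to the base year.

    National schemes are treated as independent surveys, so covariances add
    across countries on the totals scale; the index covariance follows by
    the delta method on the ratio to the base-year total.
    """
    if not completed:
        raise CombineError("no national submissions to combine")
    years = completed[0].years
    species = completed[0].species
    for sub in completed:
        if not np.array_equal(sub.years, years):
            raise CombineError("submissions must share a common year grid")
        if not sub.observed.all():
            raise CombineError(
                f"{sub.country}/{sub.species} still has missing totals; impute first"
            )
    if base_year is None:
        base_year = int(years[0])
    b = int(np.flatnonzero(years == base_year)[0])

    total = np.sum([sub.totals for sub in completed], axis=0)
    # covariance of the summed totals (independent countries)
    cov_s = np.zeros((len(years), len(years)))
    for sub in completed:
        cov_s += np.outer(sub.totals, sub.totals) * sub.covlog
    covlog_s = cov_s / np.outer(total, total)
    # log index = log S_j - log S_b
    covlog_i = (
        covlog_s
        - covlog_s[:, [b]]
        - covlog_s[[b], :]
        + covlog_s[b, b]
    )
    index = total / total[b]
    cov = np.outer(index, index) * covlog_i
    cov[b, :] = 0.0
    cov[:, b] = 0.0
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    contributing = [
        sorted(sub.country for sub in completed) for _ in years
    ]
    return EuropeanIndexSeries(
        species=species,
        euring_code=completed[0].euring_code,
        base_year=base_year,
        years=years.copy(),
        index=index,
        se=se,
        cov=cov,
        contributing=contributing,
    )


def combine_national(
    submissions: list[NationalSubmission],
    weights: pd.DataFrame,
    region_assignment: dict[str, str],
    reference_window: tuple[int, int],
    base_year: int | None = None,
) -> EuropeanIndexSeries:
    """Full combination: population scaling, regional imputation, summation."""
    scaled = compute_weights(submissions, weights, reference_window)
    filled = impute_national(scaled, region_assignment)
    return combine(filled, base_year)
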