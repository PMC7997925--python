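"""Multiplicative trend slopes and their six-class interpretation.

A trend is the average between-year relative change of the population over a
period, obtained as ``b = exp(slope)`` of a least-squares regression of log
index on year.  Values below 1 mean decline (0.95 means −5% per year),
above 1 increase.  The slope together with its 95% confidence interval
(±1.96 × SE) is classified into six classes — Steep decline, Moderate
decline, Stable, Uncertain, Moderate increase, Strong increase — using
strict threshold comparisons at 0.95 and 1.05; confidence limits landing
exactly on a threshold fall through to "Uncertain".

Trends are reported for four standard periods: 1980 onwards, 1990 onwards,
2000 onwards, and the last ten years of data.  A period whose nominal start
precedes the series is truncated to the first available year and annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .combine import EuropeanIndexSeries
from .trim import NationalIndexSeries

__all__ = [
    "ClassificationRules",
    "TrendResult",
    "PERIOD_TAGS",
    "fit_trend",
    "classify",
    "trends_for_periods",
]

CLASS_LABELS = (
    "Steep decline",
    "Moderate decline",
    "Stable",
    "Uncertain",
    "Moderate increase",
    "Strong increase",
)

PERIOD_TAGS = ("from-1980", "from-1990", "from-2000", "last-10-years")


@dataclass(frozen=True)
class ClassificationRules:
    """Thresholds of the six-class trend classification."""

    decline_threshold: float = 0.95
    increase_threshold: float = 1.05
    neutral: float = 1.00
    z: float = 1.96  # 95% confidence multiplier
    labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        if not (self.decline_threshold < self.neutral < self.increase_threshold):
            raise ValueError("thresholds must be ordered decline < neutral < increase")
        if self.z <= 0:
            raise ValueError("confidence multiplier must be positive")
        if len(self.labels) != 6:
            raise ValueError("exactly six class labels required")


@dataclass
class TrendResult:
    species: str
    euring_code: int
    base_year: int
    period: str  # one of PERIOD_TAGS
    slope: float
    se: float
    label: str
    note: str = ""


def fit_trend(
    series: EuropeanIndexSeries | NationalIndexSeries,
    period: tuple[int, int],
) -> tuple[float, float]:
    """Multiplicative slope over a period, with a delta-method standard error.

    The slope is ``exp`` of the OLS slope of log index on year.  Its variance
    is the quadratic form of the OLS contrast vector with the covariance of
    the log indices (obtained from the index covariance by the delta
    method); when the series carries no covariance the OLS residual variance
    is used instead.
    """
    lo, hi = period
    inside = (series.years >= lo) & (series.years <= hi)
    if inside.sum() < 2:
        raise ValueError(
            f"period {lo}–{hi} covers fewer than two years of the series "
            f"{series.years[0]}–{series.years[-1]}"
        )
    x = series.years[inside].astype(float)
    y = np.log(series.index[inside])
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    c = xc / sxx  # contrast: slope = c @ y
    beta = float(c @ y)
    b = float(np.exp(beta))

    cov = getattr(series, "cov", None)
    if cov is not None:
        covlog = series.covlog()[np.ix_(inside, inside)]
        var_beta = float(c @ covlog @ c)
    else:  # pragma: no cover - all series types carry a covariance
        resid = y - (y.mean() + beta * xc)
        dof = max(len(x) - 2, 1)
        var_beta = float(resid @ resid) / dof / sxx
    se_b = b * float(np.sqrt(max(var_beta, 0.0)))
    return b, se_b


def classify(b: float, se: float, rules: ClassificationRules | None = None) -> str:
    """Assign one of the six trend classes from the slope and its 95% CI.

    Significant changes (CI entirely below or above 1) are split at ±5% per
    year into steep/strong versus moderate; non-significant changes are
    Stable when the CI is contained in (0.95, 1.05) and Uncertain otherwise.
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    rules = rules or ClassificationRules()
    lcl = b - rules.z * se
    ucl = b + rules.z * se
    lo, hi, one = rules.decline_threshold, rules.increase_threshold, rules.neutral
    if ucl < lo:
        return rules.labels[0]  # Steep decline
    if lo < ucl < one:
        return rules.labels[1]  # Moderate decline
    if lcl > hi:
        return rules.labels[5]  # Strong increase
    if one < lcl < hi:
        return rules.labels[4]  # Moderate increase
    if lcl > lo and ucl < hi:
        return rules.labels[2]  # Stable
    return rules.labels[3]  # Uncertain


def trends_for_periods(
    series: EuropeanIndexSeries | NationalIndexSeries,
    rules: ClassificationRules | None = None,
) -> list[TrendResult]:
    """One classified trend per standard period the series can support.

    Decade periods (from-1980/1990/2000) are emitted when the series starts
    before the next decade boundary; a start after the nominal period start
    truncates the window and is recorded in the note.  The last-10-years
    window always covers the final ten data years (or the whole series when
    shorter, annotated).
    """
    years = series.years
    first, last = int(years[0]), int(years[-1])
    species = getattr(series, "species", "")
    euring = getattr(series, "euring_code", 0)
    results: list[TrendResult] = []

    decade_periods = (("from-1980", 1980, 1990), ("from-1990", 1990, 2000), ("from-2000", 2000, None))
    for tag, start, next_boundary in decade_periods:
        if last < start + 1:
            continue  # fewer than two years inside the nominal period
        if next_boundary is not None and first >= next_boundary:
            continue  # indistinguishable from the next, shorter period
        eff_start = max(start, first)
        note = ""
        if eff_start > start:
            note = f"period truncated to {eff_start} (scheme data start)"
        b, se = fit_trend(series, (eff_start, last))
        results.append(
            TrendResult(
                species=species,
                euring_code=euring,
                base_year=eff_start,
                period=tag,
                slope=b,
                se=se,
                label=classify(b, se, rules),
                note=note,
            )
        )

    # final ten data years, inclusive
    win_start = max(first, last - 9)
    note = "" if win_start == last - 9 else f"series shorter than ten years ({win_start}–{last})"
    if last > win_start:
        b, se = fit_trend(series, (win_start, last))
        results.append(
            TrendResult(
                species=species,
                euring_code=euring,
                base_year=win_start,
                period="last-10-years",
                slope=b,
                se=se,
                label=classify(b, se, rules),
                note=note,
            )
        )
    return results
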