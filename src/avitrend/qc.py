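"""Quality-control checks applied to national model output.

National coordinators screen an outlier report per species before results
are accepted: implausibly low (<0.5) or high (>1000) annual index values,
national species counts of a single individual or above one million, the
number of zero-count and missing-count sites, and any site contributing
more than 10% of the national species total.  A second check compares the
current run's indices, errors and trend class to a previous run.  Finally
species enter the published dataset only when their breeding population is
at least 50 000 pairs (with named exceptions) and the contributing schemes
cover at least half of it.

All threshold comparisons are strict, exactly as printed in the source
rules: an index of exactly 0.5 or a site share of exactly 10% is not
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trim import CountMatrix, NationalIndexSeries

__all__ = [
    "QCThresholds",
    "QCFlag",
    "QCReport",
    "outlier_report",
    "consistency_check",
    "species_filter",
    "FilterDecision",
]


@dataclass(frozen=True)
class QCThresholds:
    """Screening thresholds; defaults are the published rule constants."""

    index_low: float = 0.5
    index_high: float = 1000.0
    count_low: float = 1.0  # a national total of a single individual
    count_high: float = 1e6
    site_share: float = 0.10  # fraction of the national species total
    min_population: float = 50_000.0  # breeding pairs
    min_coverage: float = 0.50
    exceptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.index_low < self.index_high:
            raise ValueError("index_low must be below index_high")
        if not 0 < self.site_share < 1:
            raise ValueError("site_share must be a fraction in (0, 1)")


@dataclass
class QCFlag:
    rule: str  # which printed rule fired
    where: str  # year or site
    value: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.where}: {self.value:g}"


@dataclass
class QCReport:
    flags: list[QCFlag] = field(default_factory=list)
    n_zero_sites: int = 0
    n_missing_sites: int = 0

    @property
    def passed(self) -> bool:
        return not self.flags

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f.rule, f.where, f.value) for f in self.flags],
            columns=["rule", "where", "value"],
        )


def outlier_report(
    series: NationalIndexSeries,
    counts: CountMatrix,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """The per-species outlier report a national coordinator reviews.

    Index values outside (0.5, 1000) and national totals at 1 individual or
    above 10^6 are flagged; sites contributing more than 10% of the summed
    national species count get a dominant-site flag.  Zero-count sites and
    sites with any missing year are counted, not flagged.
    """
    thr = thresholds or QCThresholds()
    report = QCReport()
    for year, idx in zip(series.years, series.index):
        if idx < thr.index_low:
            report.flags.append(QCFlag("index below 0.5", str(year), float(idx)))
        elif idx > thr.index_high:
            report.flags.append(QCFlag("index above 1000", str(year), float(idx)))
    for year, total in zip(series.years, series.totals):
        if total == thr.count_low:
            report.flags.append(QCFlag("count of 1 individual", str(year), float(total)))
        elif total > thr.count_high:
            report.flags.append(QCFlag("count above 1e6", str(year), float(total)))

    obs = np.where(counts.mask, counts.counts, 0.0)
    site_totals = obs.sum(axis=1)
    grand = site_totals.sum()
    if grand > 0:
        for site, tot in zip(counts.sites, site_totals):
            if tot / grand > thr.site_share:
                report.flags.append(
                    QCFlag("site above 10% of national count", str(site), float(tot / grand))
                )
    report.n_zero_sites = int(np.sum((site_totals == 0) & counts.mask.any(axis=1)))
    report.n_missing_sites = int(np.sum(~counts.mask.all(axis=1)))
    return report


def consistency_check(
    current: tuple,
    previous: tuple,
    tolerance: float = 0.1,
) -> QCReport:
    """Compare a run against a previous one: class changes, index/SE shifts.

    ``current`` and ``previous`` are ``(TrendResult, index series)`` pairs
    for the same species.  Index and SE differences beyond ``tolerance``
    (absolute, on the index scale) are flagged on the overlapping years.
    """
    cur_trend, cur_series = current
    prev_trend, prev_series = previous
    if cur_trend.species != prev_trend.species:
        raise ValueError(
            f"species mismatch: {cur_trend.species!r} vs {prev_trend.species!r}"
        )
    report = QCReport()
    if cur_trend.label != prev_trend.label:
        report.flags.append(
            QCFlag(
                "trend class changed",
                f"{prev_trend.label} -> {cur_trend.label}",
                float(cur_trend.slope - prev_trend.slope),
            )
        )
    common = np.intersect1d(cur_series.years, prev_series.years)
    cur_pos = {int(y): i for i, y in enumerate(cur_series.years)}
    prev_pos = {int(y): i for i, y in enumerate(prev_series.years)}
    for year in common:
        i, k = cur_pos[int(year)], prev_pos[int(year)]
        d_idx = abs(cur_series.index[i] - prev_series.index[k])
        if d_idx > tolerance:
            report.flags.append(QCFlag("index changed beyond tolerance", str(year), float(d_idx)))
        d_se = abs(cur_series.se[i] - prev_series.se[k])
        if d_se > tolerance:
            report.flags.append(QCFlag("se changed beyond tolerance", str(year), float(d_se)))
    return report


@dataclass
class FilterDecision:
    species: str
    include: bool
    reason: str  # empty when included on the ordinary criteria


def species_filter(
    weights: pd.DataFrame,
    coverage: dict[str, float],
    thresholds: QCThresholds | None = None,
) -> list[FilterDecision]:
    """Inclusion decision per species from population size and coverage.

    A species is included when its total breeding population reaches 50 000
    pairs (or it is on the exception list of small-population species whose
    range is well covered) AND the contributing countries hold at least 50%
    of the total population.  Excluded species carry the failing criterion.
    """
    thr = thresholds or QCThresholds()
    decisions = []
    for species, grp in weights.groupby("species", sort=True):
        total = float(grp["pairs"].sum())
        cov = float(coverage[species])
        if not (0.0 <= cov <= 1.0):
            raise ValueError(f"coverage for {species!r} must be in [0, 1]")
        size_ok = total >= thr.min_population or species in thr.exceptions
        cov_ok = cov >= thr.min_coverage
        if size_ok and cov_ok:
            reason = "exception list" if total < thr.min_population else ""
            decisions.append(FilterDecision(str(species), True, reason))
        elif not cov_ok:
            decisions.append(
                FilterDecision(
                    str(species),
                    False,
                    f"coverage {cov:.0%} below {thr.min_coverage:.0%}",
                )
            )
        else:
            decisions.append(
                FilterDecision(
                    str(species),
                    False,
                    f"population {total:.0f} pairs below {thr.min_population:.0f}",
                )
            )
    return decisions
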