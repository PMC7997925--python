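"""Synthetic multi-country breeding-bird monitoring datasets with ground truth.

Real national count data behind continental bird indicators are not public,
so the pipeline ships a generator that reproduces the statistical structure
the analysis assumes: rank-1 Poisson counts (site effect × year effect) with
optional overdispersion, visit-level decomposition, schemes whose start
years differ between countries, random missing site-year cells, site strata,
a seven-region grouping of countries, and breeding-population weights.

The ground truth (site effects, year effects, the implied population-
weighted continental index) is returned alongside the data so parameter
recovery and confidence-interval calibration can be tested directly.

Year effects follow ``g_j = r**(j - base) * lognormal noise`` (noise SD 0 by
default), which makes slope recovery exact when observation noise is turned
off via ``deterministic_counts``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .trim import CountMatrix, aggregate_visits

__all__ = [
    "REGIONS",
    "SimulationConfig",
    "TrueState",
    "SchemeDataset",
    "generate_scheme",
    "inject_missingness",
    "generate_population_sizes",
]

#: default seven-region grouping of national schemes
REGIONS = (
    "Central & East Europe",
    "East Mediterranean",
    "North Europe",
    "South Europe",
    "Southeast Europe",
    "West Balkan",
    "West Europe",
)


class SimulationConfig(BaseModel):
    """Parameters of one simulated multi-country monitoring world.

    Defaults describe a moderate desk-scale world: a handful of countries
    spread over the seven regions, ~1980–2017 span, lognormal between-site
    abundance variation (median ~20 birds per plot), pure Poisson counts,
    two visits per season aggregated by their mean, 10% randomly missing
    cells, and scheme start years staggered across countries.
    """

    n_countries: int = Field(default=14, gt=0)
    n_sites_per_country: int = Field(default=20, gt=0)
    first_year: int = 1980
    last_year: int = 2017
    n_species: int = Field(default=2, gt=0)
    region_assignment: dict[str, str] | None = None
    site_effect_log_mean: float = 3.0
    site_effect_log_sd: float = 0.5
    true_trend: float | dict[str, float] = 1.0  # per species, or one shared slope
    year_noise_sd: float = Field(default=0.0, ge=0.0)
    overdispersion: float = Field(default=1.0, ge=1.0)
    scheme_start_years: dict[str, int] | None = None
    missing_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    visit_rule: str = "mean"
    n_visits: int = Field(default=2, gt=0)
    n_strata: int = Field(default=2, gt=0)
    deterministic_counts: bool = False  # emit expected counts, no sampling noise
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.last_year < self.first_year:
            raise ValueError("last_year must not precede first_year")
        if self.visit_rule not in ("mean", "max", "second_visit"):
            raise ValueError(f"visit_rule must be mean/max/second_visit, got {self.visit_rule!r}")
        if self.visit_rule == "second_visit" and self.n_visits < 2:
            raise ValueError("n_visits must be >= 2 under the second_visit rule")
        for c, y in (self.scheme_start_years or {}).items():
            if not (self.first_year <= y <= self.last_year):
                raise ValueError(f"scheme_start_years[{c!r}]={y} outside the year span")
        if self.region_assignment is not None:
            for c in self.countries():
                if c not in self.region_assignment:
                    raise ValueError(f"region_assignment missing country {c!r}")
        return self

    def countries(self) -> list[str]:
        return [f"C{k + 1:02d}" for k in range(self.n_countries)]

    def species_names(self) -> list[str]:
        return [f"Species {k + 1:02d}" for k in range(self.n_species)]

    def euring_codes(self) -> dict[str, int]:
        return {s: 10010 + 10 * k for k, s in enumerate(self.species_names())}

    def regions(self) -> dict[str, str]:
        if self.region_assignment is not None:
            return dict(self.region_assignment)
        return {c: REGIONS[k % len(REGIONS)] for k, c in enumerate(self.countries())}

    def start_years(self) -> dict[str, int]:
        """Scheme start years, staggered over (at most) the first 25 years.

        The first country of every region starts at the first year so the
        regional back-casting of later starters always has a donor; later
        cohorts within a region are spread over the early part of the span.
        """
        if self.scheme_start_years is not None:
            return dict(self.scheme_start_years)
        regions = self.regions()
        span = min(25, self.last_year - self.first_year)
        n_cohorts = max(-(-self.n_countries // len(set(regions.values()))), 1)
        seen: dict[str, int] = {}
        starts = {}
        for c in self.countries():
            p = seen.get(regions[c], 0)
            seen[regions[c]] = p + 1
            if p == 0 or n_cohorts == 1:
                starts[c] = self.first_year
            else:
                starts[c] = self.first_year + (p * span) // (n_cohorts - 1)
        return starts

    def trend_of(self, species: str) -> float:
        if isinstance(self.true_trend, dict):
            return float(self.true_trend[species])
        return float(self.true_trend)


@dataclass
class TrueState:
    """Ground truth behind a simulated dataset.

    ``site_effects`` maps country -> per-site positive effects; ``year_effects``
    maps (country, species) -> per-year positive effects with the base-year
    value exactly 1.  ``population_sizes`` are the breeding-pair weights used
    to define the implied continental index.
    """

    years: np.ndarray
    site_effects: dict[str, np.ndarray]
    year_effects: dict[tuple[str, str], np.ndarray]
    population_sizes: pd.DataFrame  # columns: country, species, pairs

    def european_index(
        self, species: str, reference_window: tuple[int, int] | None = None
    ) -> np.ndarray:
        """Population-weighted continental index implied by the truth.

        Each country's year-effect series is scaled so that its mean over the
        reference window equals the country's population size (the same
        convention the combiner applies to estimated totals); the weighted
        total is then expressed relative to the first year.
        """
        pop = self.population_sizes
        total = np.zeros_like(self.years, dtype=float)
        for (country, sp), g in self.year_effects.items():
            if sp != species:
                continue
            n = float(
                pop.loc[(pop.country == country) & (pop.species == sp), "pairs"].iloc[0]
            )
            if reference_window is None:
                ref = g[: 1]
            else:
                inside = (self.years >= reference_window[0]) & (
                    self.years <= reference_window[1]
                )
                ref = g[inside]
            total += n * g / ref.mean()
        return total / total[0]


@dataclass
class SchemeDataset:
    """Simulated visit-level and aggregated counts across all schemes."""

    visits: pd.DataFrame  # country, species, euring_code, site, year, visit, count
    counts: pd.DataFrame  # country, species, euring_code, site, year, count (NaN = missing), stratum, weight
    config: SimulationConfig

    def count_matrix(self, country: str, species: str) -> CountMatrix:
        """Site-by-year matrix for one scheme and species, NaN-masked."""
        sub = self.counts[
            (self.counts.country == country) & (self.counts.species == species)
        ]
        if sub.empty:
            raise KeyError(f"no data for {country}/{species}")
        wide = sub.pivot(index="site", columns="year", values="count")
        strata = sub.drop_duplicates("site").set_index("site")["stratum"]
        weights = sub.drop_duplicates("site").set_index("site")["weight"]
        values = wide.to_numpy(dtype=float)
        return CountMatrix(
            counts=np.nan_to_num(values),
            mask=~np.isnan(values),
            years=wide.columns.to_numpy(dtype=int),
            sites=wide.index.to_numpy(),
            strata=strata.loc[wide.index].to_numpy(dtype=object),
            weights=weights.loc[wide.index].to_numpy(dtype=float),
        )


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, cfg: SimulationConfig):
    if cfg.deterministic_counts:
        return mu.copy()
    if cfg.overdispersion > 1.0:
        # negative binomial with variance/mean ratio phi: r = mu/(phi-1), p = 1/phi
        phi = cfg.overdispersion
        r = mu / (phi - 1.0)
        return rng.negative_binomial(np.maximum(r, 1e-12), 1.0 / phi).astype(float)
    return rng.poisson(mu).astype(float)


def generate_scheme(config: SimulationConfig) -> tuple[SchemeDataset, TrueState]:
    """Draw one full multi-country dataset plus its ground truth.

    Site-year counts are Poisson (or negative-binomial) with expectation
    ``a_i * g_j``; visit counts are a multinomial split of the site-year
    count, so visit-rule aggregation stays meaningful.  Cells before a
    country's scheme start are absent; observed cells after the start are
    masked independently with ``missing_rate``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.first_year, cfg.last_year + 1)
    starts = cfg.start_years()
    pop = generate_population_sizes(cfg, cfg.seed)

    site_effects: dict[str, np.ndarray] = {}
    year_effects: dict[tuple[str, str], np.ndarray] = {}
    visit_rows = []
    count_rows = []
    codes = cfg.euring_codes()

    for country in cfg.countries():
        a = rng.lognormal(cfg.site_effect_log_mean, cfg.site_effect_log_sd, cfg.n_sites_per_country)
        site_effects[country] = a
        strata = np.array(
            [f"stratum_{chr(97 + i % cfg.n_strata)}" for i in range(cfg.n_sites_per_country)],
            dtype=object,
        )
        start = starts[country]
        active = years >= start
        for species in cfg.species_names():
            r = cfg.trend_of(species)
            g = r ** (years - cfg.first_year).astype(float)
            if cfg.year_noise_sd > 0:
                g = g * rng.lognormal(0.0, cfg.year_noise_sd, len(years))
            g = g / g[0]  # base-year effect exactly 1
            year_effects[(country, species)] = g

            mu = np.outer(a, g)  # sites x years
            x = _draw_counts(rng, mu, cfg)
            miss = np.zeros_like(x, dtype=bool)
            if cfg.missing_rate > 0:
                miss = rng.random(x.shape) < cfg.missing_rate
            for i in range(cfg.n_sites_per_country):
                for j, year in enumerate(years):
                    if not active[j]:
                        continue
                    total = x[i, j]
                    if cfg.deterministic_counts:
                        shares = np.full(cfg.n_visits, total / cfg.n_visits)
                    else:
                        shares = rng.multinomial(
                            int(total), np.full(cfg.n_visits, 1.0 / cfg.n_visits)
                        ).astype(float)
                    missing = bool(miss[i, j])
                    site = f"{country}-S{i + 1:03d}"
                    if not missing:
                        for v, c in enumerate(shares, start=1):
                            visit_rows.append(
                                (country, species, codes[species], site, year, v, c)
                            )
                    agg = (
                        np.nan
                        if missing
                        else aggregate_visits(shares, cfg.visit_rule)
                    )
                    count_rows.append(
                        (
                            country,
                            species,
                            codes[species],
                            site,
                            year,
                            agg,
                            strata[i],
                            1.0,
                        )
                    )

    visits = pd.DataFrame(
        visit_rows,
        columns=["country", "species", "euring_code", "site", "year", "visit", "count"],
    )
    counts = pd.DataFrame(
        count_rows,
        columns=[
            "country",
            "species",
            "euring_code",
            "site",
            "year",
            "count",
            "stratum",
            "weight",
        ],
    )
    truth = TrueState(
        years=years,
        site_effects=site_effects,
        year_effects=year_effects,
        population_sizes=pop,
    )
    return SchemeDataset(visits=visits, counts=counts, config=cfg), truth


def inject_missingness(
    dataset: SchemeDataset, missing_rate: float, seed: int
) -> SchemeDataset:
    """Mask each currently observed aggregated cell with probability ``missing_rate``.

    Never unmasks a cell; visit-level rows for newly masked cells are dropped
    to keep the two tables consistent.
    """
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError(f"missing_rate must be in [0, 1], got {missing_rate}")
    rng = np.random.default_rng(seed)
    counts = dataset.counts.copy()
    observed = counts["count"].notna().to_numpy()
    hit = rng.random(len(counts)) < missing_rate
    newly = observed & hit
    counts.loc[newly, "count"] = np.nan
    masked_keys = set(
        map(
            tuple,
            counts.loc[newly, ["country", "species", "site", "year"]].to_numpy(),
        )
    )
    visits = dataset.visits
    if masked_keys:
        keep = [
            tuple(k) not in masked_keys
            for k in visits[["country", "species", "site", "year"]].to_numpy()
        ]
        visits = visits[np.asarray(keep)].reset_index(drop=True)
    return SchemeDataset(visits=visits, counts=counts, config=dataset.config)


def generate_population_sizes(
    config: SimulationConfig, seed: int, *, bracket_filter_threshold: bool = True
) -> pd.DataFrame:
    """Breeding-pair estimates per country and species (strictly positive).

    With ``bracket_filter_threshold`` (default), species totals are adjusted
    so that at least one species falls below and one above the 50 000-pair
    inclusion threshold whenever two or more species are simulated, so the
    species filter is exercised by fixtures.
    """
    cfg = config
    rng = np.random.default_rng(np.uint32(seed) ^ np.uint32(0x5EED))
    rows = []
    for species in cfg.species_names():
        for country in cfg.countries():
            pairs = float(rng.lognormal(np.log(40_000), 1.0))
            rows.append((country, species, max(pairs, 1.0)))
    pop = pd.DataFrame(rows, columns=["country", "species", "pairs"])
    if bracket_filter_threshold and cfg.n_species >= 2:
        names = cfg.species_names()
        totals = pop.groupby("species")["pairs"].sum()
        lo, hi = names[0], names[-1]
        pop.loc[pop.species == lo, "pairs"] *= 30_000 / totals[lo]
        pop.loc[pop.species == hi, "pairs"] *= 400_000 / totals[hi]
    return pop
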