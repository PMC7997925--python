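"""End-to-end pipeline: simulate (or load) → fit → QC → combine → trends.

``run_pipeline`` drives the whole analysis chain from a single declarative
configuration and writes the five public dataset files.  Every stage is
deterministic given the configuration and seed, so a rerun reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import schemas
from .combine import NationalSubmission, combine_national
from .qc import QCThresholds, outlier_report, species_filter
from .simulate import SimulationConfig, generate_scheme, generate_population_sizes
from .trends import ClassificationRules, trends_for_periods
from .trim import compute_indices, compute_time_totals, fit_loglinear, fit_stratified, impute_missing

log = logging.getLogger("avitrend")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


class PipelineConfig(BaseModel):
    """Everything needed for one reproducible pipeline run."""

    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    reference_window_years: int = 3  # population weights refer to the most recent years
    stratified: bool = False
    index_scale: float = 100.0  # published index scale; 1.0 keeps the internal scale
    coverage: dict[str, float] | None = None  # species -> population coverage fraction
    apply_species_filter: bool = True
    output_dir: str = "avitrend_output"

    def with_seed(self, seed: int) -> "PipelineConfig":
        sim = self.simulation.model_copy(update={"seed": int(seed)})
        return self.model_copy(update={"simulation": sim})


def load_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


@dataclass
class PipelineResult:
    indices: pd.DataFrame
    trends: pd.DataFrame
    trends_short: pd.DataFrame
    schemes: pd.DataFrame
    species_country: pd.DataFrame
    qc_reports: dict = field(default_factory=dict)
    filter_decisions: list = field(default_factory=list)
    european: dict = field(default_factory=dict)  # species -> EuropeanIndexSeries


def run_pipeline(config: PipelineConfig, output_dir=None) -> PipelineResult:
    """Run the full chain and (optionally) write the five output files."""
    cfg = config
    sim = cfg.simulation
    log.info("simulating dataset: %s", sim.model_dump())
    dataset, truth = generate_scheme(sim)
    weights = truth.population_sizes
    regions = sim.regions()
    starts = sim.start_years()
    codes = sim.euring_codes()
    fit_fn = fit_stratified if cfg.stratified else fit_loglinear

    submissions: dict[str, list[NationalSubmission]] = {}
    qc_reports: dict[tuple[str, str], object] = {}
    grid = np.arange(sim.first_year, sim.last_year + 1)

    for species in sim.species_names():
        subs = []
        for country in sim.countries():
            cm = dataset.count_matrix(country, species)
            fit = fit_fn(cm)
            log.info(
                "fit %s/%s: converged=%s loglik=%.2f sigma^2=%.3f",
                country, species, fit.converged, fit.loglik, fit.sigma_sq,
            )
            completed = impute_missing(fit, cm)
            totals = compute_time_totals(completed)
            series = compute_indices(
                fit, totals, base_year=int(cm.years[0]), years=cm.years,
                country=country, species=species, euring_code=codes[species],
            )
            qc_reports[(country, species)] = outlier_report(series, cm)
            # place the national series on the common year grid
            full_totals = np.full(len(grid), np.nan)
            full_cov = np.zeros((len(grid), len(grid)))
            pos = np.searchsorted(grid, cm.years)
            full_totals[pos] = totals
            full_cov[np.ix_(pos, pos)] = series.covlog()
            subs.append(
                NationalSubmission(
                    country=country,
                    species=species,
                    euring_code=codes[species],
                    years=grid,
                    totals=full_totals,
                    covlog=full_cov,
                )
            )
        submissions[species] = subs

    # species inclusion filter
    coverage = cfg.coverage or {s: 1.0 for s in sim.species_names()}
    decisions = species_filter(weights, coverage)
    included = {d.species for d in decisions if d.include}
    if not cfg.apply_species_filter:
        included = set(sim.species_names())

    window_hi = sim.last_year
    window_lo = max(sim.first_year, window_hi - (cfg.reference_window_years - 1))

    idx_rows, trend_rows, short_rows = [], [], []
    european = {}
    for species in sim.species_names():
        if species not in included:
            log.info("species %s excluded by the inclusion filter", species)
            continue
        euro = combine_national(
            submissions[species], weights, regions, (window_lo, window_hi)
        )
        european[species] = euro
        for year, idx, se in zip(euro.years, euro.index, euro.se):
            idx_rows.append(
                (species, codes[species], int(year), idx * cfg.index_scale, se * cfg.index_scale)
            )
        for res in trends_for_periods(euro, ClassificationRules()):
            row = (species, codes[species], res.base_year, res.slope, res.se, res.label)
            if res.period == "from-1980":
                trend_rows.append(row + (res.note,))
            else:
                short_rows.append(row)

    indices = pd.DataFrame(idx_rows, columns=schemas.INDICES_COLUMNS)
    trends = pd.DataFrame(trend_rows, columns=schemas.TRENDS_COLUMNS)
    trends_short = pd.DataFrame(short_rows, columns=schemas.TRENDS_SHORT_COLUMNS)

    schemes = pd.DataFrame(
        [
            (
                country,
                sim.n_sites_per_country,
                f"{country} common bird monitoring",
                "point counts",
                "stratified random",
                starts[country],
                sim.last_year,
                regions[country],
                "synthetic scheme",
            )
            for country in sim.countries()
        ],
        columns=schemas.SCHEMES_COLUMNS,
    )
    species_country = pd.DataFrame(
        True, index=sorted(included), columns=sim.countries()
    )
    species_country.index.name = "species"

    result = PipelineResult(
        indices=indices,
        trends=trends,
        trends_short=trends_short,
        schemes=schemes,
        species_country=species_country,
        qc_reports=qc_reports,
        filter_decisions=decisions,
        european=european,
    )
    if output_dir is None:
        output_dir = cfg.output_dir
    if output_dir:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        schemas.write_indices(indices, out / "indices.csv")
        schemas.write_trends(trends, out / "trends.csv")
        schemas.write_trends_short(trends_short, out / "trends_short.csv")
        schemas.write_schemes(schemes, out / "monitoring_schemes.csv")
        schemas.write_species_country(species_country, out / "species_country.csv")
        qc_frame = pd.concat(
            {
                f"{c}/{s}": rep.to_frame()
                for (c, s), rep in qc_reports.items()
                if not rep.passed
            },
            names=["scheme_species", "flag"],
        ) if any(not rep.passed for rep in qc_reports.values()) else pd.DataFrame(
            columns=["rule", "where", "value"]
        )
        qc_frame.to_csv(out / "qc_report.csv")
        log.info("wrote outputs to %s", out)
    return result
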