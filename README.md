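# avitrend

National and supranational population indices and trends for breeding-bird
monitoring schemes, from site-by-year count matrices.

Every spring, volunteer fieldworkers count breeding birds on fixed study
plots under national monitoring schemes.  Turning those counts into the
continental indicators used in research and policy takes a chain of
statistical steps, and this package implements that chain as a tested,
reusable library:

1. **Visit aggregation** — per-visit counts at a plot become one site-year
   count (mean, maximum, or second visit only).
2. **National indices** — a loglinear Poisson model with multiplicative
   site and year effects, `mu_ij = a_i * g_j`, is fitted to the observed
   cells of each site-by-year matrix (the TRIM model family).  Missing
   plot-years are imputed with their fitted expectations, optionally within
   strata of similar sites.  Yearly totals over all plots become an index
   relative to a reference year, with delta-method standard errors and the
   full index covariance.
3. **Supranational combination** — national series are rescaled so each
   country's weight reflects its breeding-population size (pairs), not its
   sampling effort; countries whose schemes started late are back-cast from
   a same-region composite; the weighted totals are summed and re-indexed.
4. **Trends** — the multiplicative slope `b = exp(OLS slope of log index on
   year)` is computed for four standard periods (1980, 1990, 2000 onwards,
   and the last ten years) and classified with its 95% CI (`b ± 1.96·se`)
   into six classes: Steep decline, Moderate decline, Stable, Uncertain,
   Moderate increase, Strong increase (thresholds 0.95 and 1.05, i.e.
   ±5%/year).
5. **Quality control** — the outlier report national coordinators review
   (index outside (0.5, 1000), national totals of 1 or above 10⁶, dominant
   sites above 10% of the national count), run-to-run consistency checks,
   and the species inclusion filter (≥50 000 breeding pairs, ≥50% of the
   population covered by contributing schemes, with an exception list).

Raw national count data are not public, so the package ships a synthetic
generator (`avitrend.simulate`) that reproduces the structure the analysis
assumes — rank-1 Poisson or negative-binomial counts, visit decomposition,
staggered scheme start years, random missing cells, strata, a seven-region
country grouping, and population weights — together with the ground truth,
so parameter recovery and CI calibration are testable.

## Worked example

```python
import numpy as np
from avitrend import (CountMatrix, fit_loglinear, impute_missing,
                      compute_time_totals, compute_indices, fit_trend, classify)

cm = CountMatrix(
    counts=np.array([[12., 14.,  0., 19.],
                     [45.,  0., 61., 68.],
                     [ 8.,  9., 11.,  0.]]),
    mask=np.array([[True, True, False, True],
                   [True, False, True, True],
                   [True, True, True, False]]),
    years=np.arange(2014, 2018),
)
fit = fit_loglinear(cm)
completed = impute_missing(fit, cm)
totals = compute_time_totals(completed)
series = compute_indices(fit, totals, 2014, cm.years)
print(np.round(completed.counts, 2))
print(np.round(series.index, 4), np.round(series.se, 4))
b, se = fit_trend(series, (2014, 2017))
print(f"slope {b:.4f} se {se:.4f} ->", classify(b, se))
```

prints

```
[[12.   14.   16.8  19.  ]
 [45.   50.65 61.   68.  ]
 [ 8.    9.   11.   12.21]]
[1.     1.1331 1.3661 1.5264] [0.     0.3026 0.2385 0.2535]
slope 1.1567 se 0.0670 -> Moderate increase
```

The three missing plot-years (site 1 in 2016, site 2 in 2015, site 3 in
2017) are filled with their fitted expectations `a_i·g_j`; the yearly
totals then say the population grew by roughly half over the four years
(index 1.53 relative to 2014, ±0.25).  The average between-year change is
+15.7% per year, but with only four years the 95% CI is wide
(1.03–1.29); its lower limit sits between 1.00 and 1.05, so the trend is
classified a Moderate increase rather than a Strong one.

The same chain runs end-to-end from a declarative config, via the library
(`avitrend.run_pipeline`) or the CLI:

```sh
avitrend run-all --seed 7 --out demo_output
avitrend classify --slope 0.94 --se 0.002     # -> Steep decline
```

`run-all` writes the five public dataset files: `indices.csv` (species,
euring_code, year, index, se), `trends.csv` (…, trend, se, class, note),
`trends_short.csv` (the three shorter periods), `monitoring_schemes.csv`
(scheme metadata; `avitrend.schemas.schemes_to_xlsx` converts to
spreadsheet form) and `species_country.csv` (boolean species-by-country
contribution matrix).  Indices are published ×100 by default
(`--index-scale 1` keeps the internal scale where the base year is 1.0).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
simulates the default multi-country world with the given seed, runs the
whole chain (national fits, QC, combination, trends, classification),
writes the output files under `scratch/acceptance_run/`, and emits the JSON
report to `--out`.

## Documentation

`docs/methods.md` describes the model, the estimators and their
assumptions, the synthetic world the generator emulates, numerical choices,
and known limitations.
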