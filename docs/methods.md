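# Methods

## The national model

Counts of one species at site *i* in year *j* are modelled as independent
Poisson draws with a multiplicative structure,

    f_ij ~ Poisson(mu_ij),    mu_ij = a_i * g_j,

where `a_i > 0` is a site effect (how rich the plot is) and `g_j > 0` a year
effect carrying the population signal.  The model is identified by fixing
`g = 1` at the base (reference) year, so year effects read directly as
population change relative to that year.  This is the classical loglinear
site-plus-year model used throughout the TRIM tradition of monitoring-data
analysis.

**Fitting.**  The likelihood over the *observed* cells is maximised by
alternating the exact block updates

    a_i <- sum_j(obs) f_ij / sum_j(obs) g_j,
    g_j <- sum_i(obs) f_ij / sum_i(obs) a_i,

i.e. iterative proportional fitting restricted to the observed-cell
pattern.  Each half-step solves one block's score equation exactly, so the
log-likelihood trace is non-decreasing (this is asserted by a property
test).  Convergence requires the relative log-likelihood change to fall
below 1e-8 **and** the year effects to be stable to 1e-12 between
iterations; near an exact-fit optimum the likelihood is almost flat and the
likelihood criterion alone can stop with parameters still ~1e-3 away from
the maximum, which would violate the 1e-6 agreement with a direct numeric
optimiser that the test suite demands.  The hard cap is 10 000 iterations.

A fit is only attempted when the observed-cell pattern connects every year
to the base year through sites observed in both (checked with union-find;
the error names the unreachable years).  Sites that were surveyed but never
held the species get `a_i -> 0`; their effect is floored at 1e-12 for
evaluating `mu` (avoiding log 0) and they are excluded from the information
matrix, while still contributing their observed zeros to the totals.

**Imputation and totals.**  Missing cells are replaced by `a_i * g_j`
(observed cells are never touched), embodying the assumption that
populations on non-counted plots change like those on counted plots.  With
stratified fitting (`fit_stratified`) the model is fitted independently per
stratum, so imputation borrows only from sites with similar environmental
characteristics; stratum totals are then summed with the per-site weights.
Yearly totals are `T_j = sum_i w_i * completed_ij`, and the index is
`I_j = T_j / T_base`.

**Uncertainty.**  The covariance of the log year effects comes from the
inverse observed-cell Fisher information of `(log a, log g)` evaluated at
the MLE.  Index errors follow by the delta method,
`Cov(I_j, I_k) = I_j I_k Cov(log g_j, log g_k)`, with zero row/column at
the base year (the index is 1 there by construction).  Treating the imputed
total as a function of the year effects alone ignores the small
observed-minus-fitted residual term; a 2000-resample parametric bootstrap
on a complete 20x5 dataset agrees with the delta-method SEs within a few
percent (test tolerance 15%), and nominal 95% CIs cover the truth for
95–96% of simulated replicates.

**Overdispersion.**  Real count series are noisier than Poisson.  A
variance-inflation factor is estimated as the mean squared Pearson residual
over the residual degrees of freedom, floored at 1 (underdispersion never
shrinks errors), and multiplies all covariances.  It is on by default and
can be disabled (`overdispersion=False`); serial correlation is not
modelled.

**Visit aggregation.**  Point-count and transect schemes visit plots a few
times per season; the site-year count is the mean or maximum of visits, or
the second visit only for species whose first visit falls into migration.
Means are kept fractional — the model works on expectations and rounding
would bias low counts.

## Supranational combination

National schemes report their model output (imputed time totals, SEs,
covariances), not raw counts.  Combination has three steps:

1. **Population weighting** (`compute_weights`).  Country totals are
   rescaled by `N_cs / mean(T_cj over a reference window)`, where `N_cs` is
   the country's breeding-population estimate in pairs.  After scaling, a
   country's level equals its population, so its influence on the combined
   index is proportional to how many birds breed there — not to how many
   plots its scheme surveys (a property test doubles one scheme's counts
   and checks the combined index is unchanged).  The pipeline default
   window is the last three observed years, matching the three-yearly
   update cycle of the population estimates; the window is configurable,
   and a base-year window makes the combined index exactly the
   population-weighted mean of national indices.  Log-scale covariances are
   invariant to the rescaling.
2. **Regional imputation** (`impute_national`).  Scheme start years differ
   by decades.  Years before a country's start are filled backwards:
   `T_c,j = T_c,j+1 * (S_j / S_j+1)` where `S` sums the scaled totals of
   same-region donor countries observed in both adjacent years.  With a
   single donor this reproduces the donor's ratios exactly (closed form
   used as the test oracle).  The log-variance of each composite ratio is
   propagated by the delta method and accumulated along the chain treating
   successive ratios as independent — a simplification that slightly
   understates the covariance between imputed years; early-period errors
   are therefore approximate, which mirrors the real caveat that the
   earliest estimates rest on few schemes.  The default seven-region
   grouping is Central & East Europe, East Mediterranean, North Europe,
   South Europe, Southeast Europe, West Balkan, West Europe.
3. **Summation** (`combine`).  The continental total is the sum of scaled
   national totals; the index is its ratio to the base-year total.
   National schemes are independent surveys, so their covariances add on
   the totals scale; the index covariance again follows by the delta
   method.  Combining two identical, equally weighted countries shrinks the
   SE by sqrt(2), and 95% CIs of the combined index achieve nominal
   coverage over 1000 simulated replicates in the test suite.

## Trends and classification

The trend over a period is `b = exp(beta)`, `beta` the OLS slope of log
index on year; an exact geometric series returns its ratio to machine
precision regardless of length.  The variance of `beta` is the quadratic
form of the OLS contrast vector with the covariance of log indices
(delta method from the index covariance); `se(b) = b * sd(beta)`.  A
covariance-weighted GLS estimator was considered and rejected as the
default because the index covariance is itself estimated and the OLS slope
is the transparent, replicable choice.

Classification uses the 95% CI `(b - 1.96 se, b + 1.96 se)`:

| class             | rule                                   |
|-------------------|----------------------------------------|
| Steep decline     | upper CL < 0.95                        |
| Moderate decline  | 0.95 < upper CL < 1.00                 |
| Strong increase   | lower CL > 1.05                        |
| Moderate increase | 1.00 < lower CL < 1.05                 |
| Stable            | lower CL > 0.95 and upper CL < 1.05    |
| Uncertain         | anything else (CI overlaps 1 widely)   |

evaluated top to bottom.  All inequalities are strict; a confidence limit
landing exactly on 0.95 or 1.05 falls through to Uncertain.  These
measure-zero ties are a deterministic, documented convention.  An
exhaustive slope-by-SE grid yields exactly the six labels.

Periods: 1980, 1990 and 2000 onwards plus the final ten data years.  A
decade period is reported when the series starts before the *next* decade
boundary; a series starting inside the period is truncated to its first
year and the truncation recorded in the note field (a series starting in
2005 yields only a truncated 2000-onwards trend and the last-10-years
trend — the earlier periods would be indistinguishable duplicates).

## Quality control

The outlier report flags annual indices outside the corridor (0.5, 1000),
national yearly totals equal to 1 individual or above 10^6, and any site
holding more than 10% of the summed national species count; it also tallies
zero-count sites and sites with missing years.  All comparisons are strict,
exactly as the rules are printed: an index of exactly 0.5 or a share of
exactly 10% does not flag.  "Species counts" is read as national yearly
totals; a per-site reading would flag individual cells instead and can be
built from the same primitives.  The consistency check compares two runs
(index, SE, trend class) and flags differences beyond a tolerance.  The
species filter includes a species when its summed population is at least
50 000 pairs (or it is on the exception list of well-covered small
populations) and the contributing countries hold at least 50% of it;
excluded species carry the failing criterion.

## The synthetic world

The generator draws `a_i` lognormal (log-mean 3.0, log-SD 0.5: median ~20
birds per plot, a realistic common-species plot count), year effects
`g_j = r^(j-base)` times optional lognormal year noise (SD 0 by default, so
slope recovery is exact in the noiseless case), and site-year counts
Poisson — or negative-binomial parameterised by a variance/mean ratio when
`overdispersion > 1`, the count-data convention of the TRIM tradition.
Visit counts are a multinomial split of the site-year count, so mean / max /
second-visit aggregation is meaningful.  Defaults: 14 countries over the
seven regions (two cohorts per region, the second cohort's schemes starting
up to 25 years late, so regional back-casting always has a donor), 20 sites
per country, 1980–2017, two species, two visits aggregated by the mean, 10%
randomly missing cells, two strata, pure Poisson noise.  Population sizes
are lognormal around 40 000 pairs per country-species, with species totals
adjusted to bracket the 50 000-pair threshold so the inclusion filter is
exercised by default.

`deterministic_counts=True` replaces sampling with expected counts; the
full pipeline then recovers the generator's slope to 1e-6, which isolates
algorithmic error from Monte-Carlo error.

What the generator does **not** emulate: observer and detection effects,
habitat structure and plot-selection mechanisms (only a stratum label),
spatial or temporal autocorrelation, and species interactions.  A green
recovery test therefore establishes correctness of the estimation chain
under its own assumptions, not robustness to field realities.

## Numerical conventions

- Base-year index exactly 1 with SE exactly 0; internal scale 1.0, output
  files ×100 by default (flag-controlled) since both conventions circulate.
- Missing values are empty CSV fields; readers validate types, ranges and
  the class-label enumeration, and reject bad rows with the row number
  rather than coercing.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical config + seed gives byte-identical
  output files.
- Site-effect floor 1e-12; Fisher matrices inverted directly, falling back
  to the pseudoinverse if singular.

## Known limitations

- SEs ignore the observed-residual component of imputed totals (validated
  against the bootstrap at desk scale only).
- Cross-country independence is assumed; synchronous continental weather
  or demographic shocks would make the combined CIs anti-conservative.
- The chained-ratio variance for back-cast years ignores dependence between
  successive composite ratios and between imputed years.
- No serial-correlation correction; overdispersion is a single global
  inflation factor per fit.
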