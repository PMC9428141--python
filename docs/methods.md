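# Methods

## The estimation problem

A registry recruits `n_i` cases in county `i` (per sex stratum) out of an
unknown true count `N_i`. Where ascertainment is complete, `N_i = n_i`; in
under-ascertained counties `N_i > n_i`. The package estimates `N_i - n_i`
county by county from two inputs only: the county's base population and the
spatial contiguity structure. The working assumptions are (a) per-capita
risk is roughly homogeneous across the "normal" middle of the rate
distribution, so case counts there scale with population; (b) departures
from that relationship at the low end are under-recruitment unless the
spatial pattern says otherwise; (c) genuine risk anomalies are regional —
an environmental driver raises or lowers risk in a contiguous patch of
counties, not in a single county surrounded by unaffected ones.

## Phase 1 — statistical gap estimation

### Reference selection

Counties are ranked by incidence rate `r_i = n_i / pop_i * 100000`
(per-period, not annualized; the scale is configurable). Three methods
propose a "normal" band on this ranked series:

- **z-score band**: counties with `|r_i - mean| / sd < z` (mean and sample
  sd over *all* counties, zeros included; default levels 0.25, 0.5, 0.75).
  The reported bounds are the minimum and maximum *observed* rates among
  admitted counties, not the analytic `mean ± z·sd` — this matches how such
  ranges are conventionally tabulated and keeps them on the scale of real
  counties.
- **straight section**: the longest run of consecutive non-zero-rate
  entries whose step differences stay below `max_diff` (default twice the
  median step) and step ratios below `max_ratio` (default 1.15), with at
  least `min_length` (default 8) members; among equally long runs the one
  whose median rate is closest to the mean. This is a deterministic
  surrogate for what is otherwise a visual judgement of flatness, which is
  the main reason it needs thresholds at all.
- **Jenks natural breaks**: exact minimization of within-section squared
  deviation over contiguous partitions of the sorted rates (Fisher's
  dynamic program; ties broken toward the lowest first break). The section
  whose observed [min, max] interval contains the unweighted mean rate is
  the proposed band; a mean falling on a break or in a gap between sections
  selects the higher section. `k` defaults to 5 and is configuration — there
  is no principled universal `k`, and 4–5 sections is the conventional
  choice for series of under ~100 areal units.

The **consensus** intersects the three rate intervals (members recomputed
from the rates). Counties *below* the consensus band are targets; counties
above it are treated as fully recruited hotspot members, and together with
the reference counties form the "non-target" set used in validation.

Unattended runs need determinism where the original workflow had a human in
the loop, so the pipeline (not the individual operations, which keep strict
error contracts) applies two fallbacks, both logged: if no flat run exists,
`max_diff` is doubled up to three times (the run-length floor halves, to no
less than 4, on the last try); if the intersection is empty or admits fewer
than 3 counties — too few for a two-parameter GLM — the consensus falls back
to majority rule (county admitted by ≥ 2 of 3 methods). On noisy data the
straight-section method is the usual dissenter: heavily thinned counties
form their own low, flat shelf in the ranked series that can out-length the
true middle section.

### Poisson regression and prediction

`N_i ~ Poisson(mu_i)`, `log mu_i = b0 + b1 ln(pop_i)`, fitted to reference
counties by IRLS (statsmodels GLM, convergence tolerance 1e-10). An
intercept is included by default — the standard GLM formulation — with a
no-intercept switch for sensitivity analysis. The fit requires ≥ 3 reference
counties and a non-degenerate design. For every county the linear
prediction `eta_i` and its standard error `sqrt(x' V x)`, `x = (1, ln
pop)`, give `mu_i = exp(eta_i)`; target counties get `u_i = max(mu_i - n_i,
0)`.

### Monte Carlo intervals

Per replicate one coefficient vector is drawn from `MVN(b_hat, V)` and
applied to every target county: `eta*_i = b0* + b1* ln(pop_i)`, `u*_i =
max(exp(eta*_i) - n_i, 0)`. Each county's `eta*_i` is marginally
`Normal(eta_i, se_i)`; drawing at the coefficient level makes counties
within a stratum properly correlated, which matters for totals — with
independent per-county draws the parameter uncertainty shared by all
counties averages out of the sum and the total's interval collapses to a
fraction of its correct width. Intervals are empirical 2.5th/97.5th
percentiles of 10,000 draws (configurable); sex-specific draw streams are
reused (summed within a draw) for the grand total. Sampling on the log
scale keeps every `mu*` positive; negative per-county draws are truncated
at zero before summation, which adds a small conservative (upward) skew.

These intervals quantify uncertainty in the *expected* missing count given
the fitted model. They are not prediction intervals for the realized
missing count: the Poisson realization noise of the unobserved cases
(variance ≈ the expected missing count itself) is outside their scope, so
against a simulated realized truth their coverage is structurally below
nominal (measured ≈ 74% on the default scenario, vs ≈ 86% against the
designed expectation). A parametric-bootstrap prediction interval (adding a
Poisson draw on top of `exp(eta*)`) would cover the realization but is a
different estimand from the one this procedure defines.

### Reporting conventions

Summaries follow the conventions of registry tables: per stratum the
fractional unrecruited total, its half-up-rounded integer `R`, `R /
(recruited_in_target + R)` and `R / (recruited_all + R)` as percentages;
the total row's rounded integer is the *sum of the per-stratum rounded
integers*, not the rounding of the summed fraction (36 + 83 = 119 even
when the fractions sum to 118.35).

## Phase 2 — spatial adjustment

Raw small-area rates are unstable (the small number problem), so rates are
first standardized à la Assunção–Reis: with overall rate `beta = sum(counts)
/ sum(pops)` and variance component `alpha = max(0, s2 - beta / mean(pop))`
(`s2` the population-weighted variance of raw rates about `beta`),
`z_i = (r_i - beta) / sqrt(alpha + beta / pop_i)`.

Local Moran's I on the centered deviations `y_i` uses row-standardized
contiguity weights: `I_i = (y_i / m2) * sum_j w_ij y_j`, `m2 = sum(y^2)/n`;
the mean of `I_i` equals the global Moran's I (tested against direct
double-sum evaluation). Significance is by conditional permutation: the
focal value is held fixed and the remaining values are randomly reassigned
to its neighbour positions (999 draws by default, minimum 99; an exact
enumeration mode exists for tiny graphs); the pseudo p-value is one-sided
in the direction of the observed lag, `(extreme + 1) / (n_perm + 1)`.
Quadrants HH/LL/HL/LH require significance at 0.05 (configurable); zero
deviation, zero lag, `m2 = 0`, or an island (no neighbours, logged) give NS.

By default the analysis runs on *post-estimation* rates (expected counts
for targets, recruited counts elsewhere), because the adjustment corrects
the statistical estimates, which already embody the recruited data; a
switch allows raw recruited rates for sensitivity. Only **target** counties
flagged LH or HL are adjusted: the focal county's rate is replaced by the
population-weighted mean of its neighbours' rates (self excluded by
default; `include_self` covers the alternative reading of a neighbourhood),
and the implied count `smoothed_rate * pop / 100000` raises an LH county's
estimate or lowers an HL county's, floored so the expected count never
drops below the recruited count and `u_i >= 0`. All other counties pass
through bit-identically.

## Validation

Pearson correlations between county case counts and mortality counts, on a
3 × 3 × 3 grid: stratum (female, male, both summed per county) × county
subset (non-target, all, target; for the combined stratum the target set is
the union of the per-stratum target sets) × case base (recruited only,
after statistical estimation, after spatial adjustment). Counts, not rates,
are correlated. Cells with fewer than 3 counties, a constant vector, or
missing mortality are absent, not zero.

## Synthetic scenarios

The generator emulates the data-generating assumptions the method rests on:
counties on an `n x n` queen-contiguity lattice (no geometry files needed,
and Moran quantities stay analytically checkable); per county × stratum a
LogNormal population (defaults mu = ln(100000), sigma = 0.5 — median
stratum population 100k, about the scale of mid-size counties, so the
default base rate of 5 per 100,000 per period yields ~5 expected cases per
stratum); true counts Poisson with optional planted contiguous
hotspot/coldspot multiplier blocks; a fraction of counties (default 0.3,
spatially random; a clustered mode exists as the deliberately hard case)
recruit only `Binomial(true, 0.4)` of their cases; mortality is
`Binomial(true, 0.8)` of the TRUE counts, mirroring the premise that
mortality sees unrecruited cases too. All randomness flows from one seed;
identical seeds give byte-identical scenario files.

What the generator does *not* emulate — real county geometry, age
structure, spatially correlated recruitment propensity tied to provider
networks, migration between diagnosis and death, temporal drift — bounds
what passing tests show: they validate the estimation machinery under the
method's own assumptions, not the assumptions themselves.

## Numerical and design choices

- Rate ties in the ranking are broken by county id; all set-valued outputs
  are sorted before use, so every stage is deterministic given its seed.
- Sub-seeds are derived per stratum and per consumer (Monte Carlo,
  permutation) from the top-level seed via `SeedSequence`, kept below 2^31.
- The Jenks DP reconstructs cuts left-to-right taking the shortest first
  section that preserves optimality, yielding the lowest-first-break
  partition among ties.
- `alpha` in the EB standardization is floored at 0; a zero denominator
  (possible only with `alpha = 0` and `beta = 0`) yields `z_i = 0`.
- Percentile intervals use the default linear-interpolation empirical
  quantile.
- Degenerate inputs fail loudly and early: zero populations, duplicate
  county/stratum pairs, asymmetric or dangling adjacency references,
  constant rate vectors for the z-band, `k` above the number of distinct
  values, designs with equal populations, `n_perm < 99`.

## Known limitations

- Counties below the reference band for benign reasons (sampling noise at
  small expected counts, true cold spots) are attributed unrecruited cases;
  the method over-estimates in cold spots by construction, and the spatial
  phase only corrects the significant outliers among them.
- The Monte Carlo interval is not a prediction interval (see above).
- Reference selection assumes under-recruitment is not so widespread or so
  clustered that it forms the majority of the "normal-looking" band; the
  clustered generator mode exists precisely to probe this failure mode.
- Correlation-based validation is indirect: proportional errors that
  preserve ranking inflate `r` without implying count accuracy.
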