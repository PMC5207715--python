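# Methods

## Model

The package estimates a multi-species geometric-mean abundance index.
Each monitored population i contributes annual log10 rates of change
d_{it} = log10(N_{it}/N_{i,t−1}); a species' trend is the equal-weight
mean of its populations' rates per year; group and higher-level trends
are (weighted) means of lower-level trends per year; and the index is the
cumulative product I_t = I_{t−1}·10^{d̄_t}, fixed to 1 in the baseline
year. Averaging always happens on the lambda scale and the conversion to
index values is the very last step, so the index is the geometric mean of
relative abundance across species.

Assumptions inherited from this construction:

- each population's measure is internally consistent over time but its
  units are arbitrary — the index is invariant to rescaling any single
  series (a tested property);
- species within a group are exchangeable: no phylogenetic or abundance
  weighting below the group level;
- a year's group trend is estimated from whichever members have data that
  year (weights renormalized over those present), which assumes data are
  missing at random within groups.

## Population trend estimation

**Smoother.** Series with at least `gam_min_points` (default 6) observed
years are smoothed with a generalized additive model consisting of a
single penalized cubic B-spline smooth of log10 abundance on year:
clamped uniform knots, basis dimension ⌈n/2⌉ (minimum 3), a
second-difference penalty on the coefficients, and the penalty weight
selected by generalized cross-validation over a fixed grid (0 and 31
log-spaced values in 10⁻⁵…10⁵). The fit is evaluated at every year from
the first to the last observation and then differenced. The grid search
is deterministic, so identical inputs give identical fits.

**Poor-fit rule.** The published methodology excludes "poor GAM fits"
without defining them; here a fit is rejected — and the series chained —
when the optimization fails, any fitted value is non-finite, or the
fitted log10 values leave the observed log10 range by more than
`gam_fit_margin` (default 1.0) orders of magnitude. The rule is
deliberately conservative and configurable.

**Chain method.** Shorter or rejected series are log-linearly
interpolated between observations (observed values kept bitwise exact)
and differenced directly. Interpolation distributes the total log change
uniformly across a gap, so the telescoping identity
Σ d_t = log10(N_last/N_first) holds exactly.

**Zero counts.** log ratios are undefined at zero, so if a series
contains a zero the whole series is shifted by 1% of its mean
(`zero_adjust_fraction`); all-zero series are dropped with a warning.
The 1% convention is the smallest intervention that keeps every rate
finite while leaving non-degenerate series essentially unchanged.

**Capping.** Annual rates are clipped to ±`cap` log10 units/yr (default
1.0, i.e. a tenfold change), guarding the mean-based aggregation against
single-survey artefacts; capping can be disabled (`cap=None`), and the
exact-identity tests run with it off.

## Hierarchies and weights

The unweighted hierarchy averages species within the six zone × system
subsets, systems equally within zone, zones equally. The published
description fixes this order (systems within zone first); because the two
orderings differ when subsets are missing years, the alternative
(zones within system first) is available via
`assemble_lpi_u(..., order="zones_within_system")`.

The weighted hierarchy uses a `WeightScheme` of proportional weights:
taxon within realm × system, realm within system, system (equal by
default). Weights are renormalized to sum to one within each parent on
construction, and again each year over the children that have data. The
weighted combination is implemented as the weighted arithmetic mean
Σ w_j d̄_{jt} (not additionally divided by the number of groups): with
proportional weights that is the only form that reduces to the plain mean
under equal weights and keeps the index continuous as groups enter or
leave the record.

A year in which *no* child anywhere has data cannot be renormalized away;
`lambdas_to_index` raises by default and can carry the index across the
gap (`on_missing="hold"`, used inside the bootstrap where resampling can
empty a thinly covered year).

## Bootstrap intervals

Species are resampled with replacement within their lowest-level group
(zone × system for LPI-U, system × realm × taxon for LPI-D), preserving
group sizes so the weights keep their meaning; the full hierarchy is then
recomputed. Percentile bounds (2.5/97.5 at the default 95% level) are
taken per year across iterations; the point estimate is always the
non-resampled index. The published default is 10,000 iterations; tests
and the acceptance script use 200, which is enough for stable 95% bounds
at the group sizes simulated. One seed drives all iterations, so results
are bit-reproducible. The percentile method does not guarantee
ci_low ≤ point ≤ ci_high and the package does not assert it; it does
guarantee (and tests) ci_low ≤ ci_high > 0 and zero width at the
baseline. Uncertainty from the smoother itself is not propagated.

## Representation diagnostics

Coverage tables compare, within each realm, a taxon's share of dataset
species against its share of known species, via a 2×2 chi-squared test of
equal proportions. Yates' continuity correction is applied by default and
can be toggled — the published tables do not state the convention, and
their inputs are printed as rounded proportions, so exact reproduction of
printed statistics is not a meaningful target; direction labels
(over/under) are. No multiple-testing correction is applied, matching the
per-cell presentation of the original tables; callers can correct the
returned p-values if desired. Red List comparisons use the five
categories LC, NT/LR, VU, EN, CR (NT and LR merged), and the
Criterion-A-only variant drops threatened species without a
population-reduction listing from the dataset side while switching the
reference counts to their Criterion-A analogues (`count_a`).

## Synthetic data

The generator emulates the structure of literature-compiled population
databases: groups of species with group-specific true annual
multiplicative rates r_g, one or more populations per species, initial
abundances log-uniform in [10, 10⁴] (units heterogeneity), lognormal
observation noise (normal with sd `obs_noise_sd` on log10 abundance —
the conjugate of the log-ratio pipeline, keeping expected lambdas
unbiased), series spans placed uniformly in the window with uniform
lengths, and per-year missingness with the ≥ 2-observation rule enforced.
Defaults: the 1970–2012 window, noise sd 0.05, full-window series, no
missingness — the conditions used by the recovery experiments.

Because the truth is constant exponential growth per group,
`true_index` gives the exact expected index by nested weighted means of
log10 r_g. What the generator does *not* emulate — density dependence,
trend autocorrelation, observation error that scales with abundance,
spatial structure, non-random missingness — bounds what passing tests
show: they validate the estimator machinery, not robustness to every
real-world failure mode.

## Verification problem sizes

The test suite and acceptance script use: 50 random series for the exact
chain identities; a four-group, two-realm fixture for the closed-form
oracle (tolerance 1e-10 relative); 1,000 random 2×2 tables for the
chi-squared oracle (1e-9); and 100 simulation replicates × 200 bootstrap
iterations × 200 species for interval coverage (pass bar: ≥ 90% coverage
at the nominal 95% level). These sizes make the whole suite run in about
two minutes on one CPU while keeping Monte Carlo error well inside the
pass margins.

## Known limitations

- The smoother is a single-smooth Gaussian GAM on log10 abundance;
  count-likelihood GAMs and observation-error state-space models are out
  of scope.
- Weight schemes must already use merged taxa/realms; the reader merges
  labels in population tables but will reject duplicate weight keys
  rather than summing them.
- Representation tests treat species lists as fixed and exhaustive;
  uncertainty in known-species counts is not propagated into the index
  weights.
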