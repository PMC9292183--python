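# Methods

## Model

The simulator is an individual-based model of a female-only,
stage-structured population with overlapping generations.  An individual
is the triple (s, μ, f): a continuous developmental state s on [0, 3] and
two heritable life-history traits, maturation rate μ (state units per
day) and fecundity f (offspring per day).  Stages are classified from s:
juvenile on [0, 1), adult on [1, 3), death of age at 3.  All rates are on
the daily scale.

Traits trade off twice.  Between each other: f = 1/(4μ), so the founding
maturation-rate range [0.02, 0.04] maps exactly onto fecundities
[12.50, 6.25] — fast maturation buys low reproductive output.  Against
survival: juveniles die at Poisson rate 5μ, adults at rate 0.001·f, so
each trait also raises its carrier's stage-specific hazard.  Hazards are
discretised per one-day step as p = 1 − exp(−rate·dt), which is exact for
a Poisson process observed on a fixed grid.

Reproduction is continuous: each adult appends Poisson(f) newborns per
day at s = 0.  Inheritance is imperfect — offspring traits are parental
copies plus independent zero-mean Gaussian errors, one per trait, floored
at 10⁻⁶ to preserve positivity.  Because both traits mutate
independently, the trade-off holds exactly only in the founding
generation and drifts thereafter; this mirrors inheritance of two
correlated traits rather than re-deriving one from the other.

Density dependence removes N·0.001·(1 + N/250000) random individuals per
day regardless of stage (baseline mortality 0.001 in a typical 10 L
pool); the expectation is realised as floor + Bernoulli(fraction), so a
single realisation never deviates from the expectation by more than one.

Disturbance is juvenile-specific: an event removes an exact rounded 30%
of juveniles, drawn uniformly without replacement — mirroring the
discard of a fixed 30% volume of well-mixed medium rather than per-capita
coin flips.  Schedules are deterministic (events at every multiple of the
period: 3 days = Fast, 14 = Slow) or stochastic (the same number of
events at integer days drawn uniformly without replacement), so regime
pairs are event-count matched and differ only in temporal arrangement.
Event days are drawn on the integer grid because the engine advances in
whole days; two events in one day would be indistinguishable.

## Within-day ordering

The order of demographic processes within a day is a modelling choice,
centralised in `engine.step`: (1) disturbance, (2) growth and
end-of-life deaths, (3) hazard mortality, (4) reproduction, (5) density
removal on the post-birth roster.  Newborns are exempt from sub-steps 1–3
on their birth day (no death before existing for a full day) but are part
of the end-of-day census that density dependence acts on.  The
`newborn_same_day_hazards` switch exposes the alternative in which
newborns face juvenile hazard immediately.  Stage for hazard mortality is
evaluated after growth, so an individual crossing s = 1 in the morning
faces adult mortality that same day.

## Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `initial_n` | 5000 | individuals | founding size, 25:1 juveniles:adults |
| `horizon` | 150 | days | ~5–6 generations |
| `period` | 3 or 14 | days | Fast / Slow disturbance periodicity |
| `mu_min`, `mu_max` | 0.02, 0.04 | 1/day | founding maturation-rate range |
| `juvenile_mort_coeff` | 5 | — | juvenile hazard = 5μ |
| `adult_mort_coeff` | 0.001 | — | adult hazard = 0.001·f |
| `dd_base`, `dd_scale` | 0.001, 250000 | — | density-dependent removal |
| `disturbance_fraction` | 0.3 | — | juveniles removed per event |
| `mutation_scale` | 0.01 | — | inheritance-error scale (see below) |
| `scale_factor` | 1 | — | proportional shrink of `initial_n` and `dd_scale` |

The inheritance-error scale "0.01 of the founding trait mean" is
ambiguous between a variance and a standard deviation.  Read as a
variance it gives an error SD of ~0.017 on μ — as wide as the whole trait
range, which destroys parent–offspring resemblance and contradicts the
intent of a small copying error.  The default therefore interprets it as
the SD (1% of the founding mean, ~3×10⁻⁴ on μ); the literal-variance
reading remains available via
`DemographyParams(mutation_noise_interpretation="variance")`.

`scale_factor` shrinks `initial_n` and `dd_scale` together, preserving
per-capita density dependence at equal relative density.  The test
ensembles use 0.1 (500 founders, density constant 25,000) with 20
realisations per regime over 150 days and 10 per deterministic regime
over 300 days — sizes chosen so an ensemble study completes in seconds
while keeping the regime contrasts statistically detectable.

## Emergent dynamics and extinction

Under the default parameterisation, juvenile survival to maturity is
approximately e⁻⁵ from the trait-linked hazard (the cumulative hazard
5μ·(1/μ) is trait-independent) times 0.7 per disturbance experienced.
Fast regimes hit a maturing cohort ~8–11 times, putting lifetime
reproductive success near 0.1; Fast populations therefore decline toward
extinction over a few generations, and many desk-scale realisations are
extinct by day 150 and essentially all by day 300.  This is intrinsic to
the parameterisation, not an artefact: the transient trait dynamics (an
early proliferation of fast reproducers, then a compensatory resurgence
of fast maturers) and the rapid collapse of trait variance in Fast
regimes play out during that decline.  Extinct (or single-survivor)
populations have no defined trait variance; variances are recorded as
missing, never zero, and ensemble summaries average over the surviving
realisations.  Consequently long-horizon Fast ensembles at reduced scale
may have *no* surviving realisation, in which case a Fast ensemble mean
at day 300 is undefined and comparisons against it cannot be formed.

## Statistics

Per-population trait variance is the sample variance (n−1 denominator)
over living individuals.  Ensembles are compared with Welch's two-sample
t-test on log-transformed per-realisation variances (unequal sizes and
spreads; the log makes the heavily right-skewed variances roughly
symmetric); degrees of freedom are Welch–Satterthwaite.

The permutation test targets replicate-structured designs: treatments A
and B with a and b replicate populations, each contributing
individual-level measurements.  The observed statistic is
mean(replicate variances of B) − mean(replicate variances of A).  The
null is built by (1) pooling all measurements across all treatments and
replicates, (2) drawing N = a + b groups of `group_size` = 30
measurements (without replacement within a group, independently across
groups) and taking each group's variance — the universal PDF — then (3)
resampling b and a variances from it with replacement 50,000 times and
recording the mean difference.  The one-sided p-value is the plain
proportion of null differences ≥ the observed one (weak inequality, no
+1 correction), with B the hypothesised-larger treatment.  The universal
PDF is drawn once by default, which makes the null supported on few
values; `pdf_oversample` enlarges it and `redraw_universal_pdf` re-draws
it each iteration for users who want a smoother null, and `pool_scope`
restricts pooling to the two compared treatments.  Replicates with a
single measurement feed the pool but cannot contribute a replicate
variance.  Calibration: on exchangeable synthetic datasets the test's
p-values are approximately uniform and its rejection rate at α = 0.05 is
nominal (verified over 500 datasets in the test suite); against a
fourfold variance inflation its power exceeds 0.8.

## Synthetic measurement campaigns

The experiment emulator reproduces the *shape* of the lab measurement
protocol: 3 treatments × 8 replicates × 30 females; per female a mean
clutch interval and a mean offspring age at sexual maturity, both
quantised to a 0.5-day grid (12-hour checks); fecundity = mean clutch
size 47.32 / interval, which is exactly invertible on the grid.  Latent
ages and intervals are lognormal — positive and right-skewed like real
interval data — with baseline medians of 35 days (maturity) and 4.5 days
(clutch interval), inside the ranges the trait bounds imply (25–50 days;
3.8–7.6 days), and a baseline log-SD of 0.15.  Treatment effects scale
the median and the log-variance per trait; a replicate-level lognormal
random effect (default off) induces within-treatment correlation.  The
emulator makes no attempt to model husbandry (food, temperature, mating
protocol) or clutch-size variation between females, which the protocol
itself fixed at the global constant; what passing tests show is that the
statistics layer is calibrated for data of this structure, not that the
generator reproduces any particular real campaign.

Simulation endpoints can be pushed through the same measurement protocol
(`simulate_endpoint_measurement`): survivors are subsampled without
replacement into replicates of 30, their implied ages (1/μ) and intervals
(47.32/f) quantised to the grid.  It raises an explicit
insufficient-sample error when fewer than 30 survivors exist — the
in-silico analogue of a failed replicate.

## Numerical and reproducibility notes

All randomness flows from a single seed per run through numpy's
seed-sequence tree; ensemble realisation seeds are spawned children of
the master seed, so ensembles are reproducible without seed collisions.
Identical (config, seed) pairs give bit-identical trajectories, and data
files embed the config hash and seed (timestamps live only in the run
manifest), so identical runs write byte-identical files.  Degenerate
inputs are defined: an empty population steps through all sub-steps
unchanged; variance of fewer than two values is an error in the stats
layer and NaN in step records; a disturbance with no juveniles removes
nothing.

## Known limitations

No spatial structure, migration, temperature or food dynamics; females
only, no explicit mating or recombination; no autocorrelated (coloured)
disturbance schedules; normality diagnostics before the Welch tests are
out of scope.  The eigenvalue fitness-landscape analysis that complements
this simulator in the wider study is not part of the package.
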