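# Methods

## Scope and data model

The package takes raw presence-only occurrence records — rows of (taxon
group, species name, grid reference, event date) — and produces annual
Bayesian occupancy estimates per region and long-term growth-rate trends
per species. The spatial unit is the 1 km grid cell (monad) on the British
or Irish national grid; the temporal unit of the state process is the
calendar year (the closure period), and the replication unit of the
observation process is the *visit*: a unique (cell, date) combination.
Regions are the UK countries; reported outputs add the GB aggregate
(England + Scotland + Wales) and, where Northern Ireland is covered, the
UK aggregate.

## Standardisation rules

Records are reduced to a uniform precision before modelling:

- **Location.** Grid references are parsed with their precision inferred
  from digit count (2n digits → a square of side 10^(5−n) m) and from
  tetrad (DINTY letter, 2 km) or quadrant (NE/NW/SE/SW, 5 km) suffixes.
  References at 1 km or finer are truncated to their enclosing monad;
  coarser references are rejected. Truncation keeps the leading two digits
  of each coordinate group; e.g. `SU123456` (a 100 m square at easting
  12300 m, northing 45600 m within SU) lies in monad `SU1245`.
- **Date.** Only day-precision dates are usable, because within-year
  replicate visits are what identify detectability. Accepted dialects are
  ISO `YYYY-MM-DD` and `DD/MM/YYYY`; year-only and year-range strings are
  rejected as imprecise, everything else (including two-digit years, whose
  century is ambiguous) as unparseable. The study window is 1970–2015.
- **Territory.** Cells are mapped to regions by an explicit lookup table
  rather than polygon GIS; cells absent from the lookup are rejected as
  outside the territory. Northern Irish cells keep their native Irish-grid
  labels.
- **Names.** Records identified above species rank (bare genera,
  `sp.`/`spp.`) are dropped first. A decision table then maps synonyms,
  renames aggregates (`agg.`, `s.l.` names kept verbatim), drops excluded
  names, and flags retain-no-model names — which stay in the data so that
  list lengths are fully informed, but get no model fit. Synonym chains
  are followed to their terminus; cycles are a configuration error.
- **Deduplication.** Exact duplicates on (canonical species, monad, day)
  are removed last, after truncation and renaming, so records that become
  identical through standardisation deduplicate too.

Every rejection is counted by reason and the identity
`raw = clean + rejected` is asserted on every run.

## Detection histories

Visits are built once per dataset (not per species): the list length of a
visit counts distinct species recorded at that (cell, date), including
retain-no-model names, and is used categorically — length 1, 2–3, or 4+ —
as the effort covariate. Sites with visits in fewer than `nyr = 2`
distinct years are dropped; survival depends on visit years, not on focal
detections, and the same filtered visit set serves every focal species in
the group. The focal species' history is the 0/1 detection vector over
these visits; occupancy is modelled for every year on the study axis, so
years without data still receive (appropriately uncertain) estimates.

## Model and priors

State: `z_it ~ Bernoulli(psi_it)`, `logit(psi_it) = b_{t,r(i)} + u_i`.
Observation: `y_itv | z_it ~ Bernoulli(p_itv z_it)`,
`logit(p_itv) = a_t + beta1·[L in 2–3] + beta2·[L ≥ 4]`. No false
positives: a detection forces `z_it = 1`.

Priors (all scales are standard deviations, configurable via
`PriorConfig`):

| parameter | prior | default scale |
|---|---|---|
| `b_{1,r}` | Normal(`mu_br`, ·) | 100 |
| `b_{t,r}`, t>1 | Normal(`b_{t−1,r}`, `sigma_br`) | — |
| `mu_br` | Normal(0, ·) | 10 |
| `sigma_br`, `sigma_u`, `sigma_a` | half-Cauchy(·) = \|Student-t, 1 df\| | 1 |
| `u_i` | Normal(0, `sigma_u`) | — |
| `a_t` | Normal(`mu_a`, `sigma_a`) | — |
| `mu_a` | Normal(0, ·) | 10 |
| `beta1`, `beta2` | Normal(0, ·) | 10 |

The first-year and hypermean scales are read as variance specifications
(10^4 and 100) converted to SDs of 100 and 10. Gibbs-sampler conventions
elsewhere parameterise normals by precision; because the stated intent is
a vague prior either reading is serviceable, and the scales are exposed as
configuration rather than constants.

## Sampler

Data-augmented Metropolis-within-Gibbs, all updates vectorised:

- `z` — exact closed-form conditional. Detected site-years are 1; site-years
  with undetected visits use Bayes' rule with the probability of the
  all-zero record; unvisited site-years draw straight from `psi_it`.
- `b` — elementwise random-walk Metropolis on an odd/even year
  checkerboard, so each update's random-walk neighbours are held fixed and
  the parallel acceptance is exact.
- `u`, `a` — independent elementwise Metropolis (site conditionals are
  independent given `b`; year conditionals given the rest).
- `beta1`, `beta2` — scalar Metropolis.
- `mu_br`, `mu_a` — conjugate normal draws.
- SD parameters — Metropolis on log scale with the half-Cauchy prior and
  the log-parameterisation Jacobian.
- joint scale (interweaving) moves — each (effects, SD) pair is also
  updated by a proposal that rescales the effects and their SD together
  (`u` with `sigma_u`; `a` about `mu_a` with `sigma_a`; each region's
  random-walk increments about `b_1` with `sigma_br`). The Gaussian
  quadratic form is invariant under the map, so the acceptance ratio needs
  only the data-likelihood change, the half-Cauchy change and one
  Jacobian `log c` term. Without these moves the sigma–effects funnel
  mixes diffusively, which simulation-based calibration detects as
  U-shaped rank histograms for `sigma_u`.

Step sizes adapt by Robbins–Monro toward 0.44 acceptance during burn-in
only, so the post-burn-in chain is a fixed-kernel Markov chain. Initial
values: `z = 1` wherever detected and Bernoulli(0.5) elsewhere; continuous
parameters from Normal(0, 0.1); SDs offset to 0.5 + |Normal(0, 0.1)|; a
bounded retry re-draws the start if the joint density is non-finite.
Chains are seeded per (master seed, chain index) with PCG64 streams; runs
are bit-reproducible. Defaults are 40,000 iterations, 20,000 burn-in,
thinning 3, 3 chains, with a 20,000/10,000/3 "large" preset for data-rich
groups.

Convergence is reported as the classic Gelman–Rubin potential scale
reduction factor (between/within chain variance form) on the derived
occupancy and the monitored hyperparameters, with 1.1 as the conventional
adequacy threshold; estimates are *reported* with their Rhat rather than
filtered by it, and all-constant chains (e.g. saturated occupancy) are
flagged degenerate and reported as 1.

## Derived quantities and products

Annual occupancy is the finite-sample proportion of occupied sites,
`psi_fs[r,t] = mean_{i in r} z_it`, over all modelled sites of the region
in every year — including sites unvisited that year, whose `z` draws carry
the model's uncertainty. Products are: 1000 posterior samples per
region-year (sampled without replacement, same draw indices across all
regions and years of a species so joint structure is preserved); summary
tables (mean, 2.5%/97.5% type-7 quantiles, SD, Rhat; 3 dp on export); and
per-species trends. The trend for a species uses, per sample, the
occupancy at the first and last years with records of that species,
`y` = inclusive year count (last − first + 1, the published N_Years
convention; the span convention is available for sensitivity checks).
Samples with zero starting occupancy — possible since `psi_fs` is a
finite-site proportion — are excluded and counted, the growth rate being
undefined there. Precision is 1/variance (n−1 denominator) of the sample
growth rates; all-identical trends report infinite precision with the
degenerate flag visible in the value. Species enter the trend table only
with ≥ 50 records and no interior run of more than 10 recordless years;
edge gaps are handled by clipping the trend span instead.

## Synthetic data generator

The generator emulates the statistical structure the model assumes plus
the messiness the standardiser must handle. Truth: regional random walks
(optionally with per-year drift to create known trends), site effects,
`z` draws, and the exact `psi_fs` they imply. Records: Poisson visits per
site-year (intensity may vary over years to mimic uneven recording),
visit dates uniform within year, list lengths from a zero-truncated
negative binomial (mean 1.6, dispersion 0.9 by default, reproducing the
heavy skew toward single-species lists seen in real scheme summaries),
focal detection from the model's own observation process, and background
species names filling the list. Site labels are synthesised on a valid
100 km square per region — Northern Ireland on the Irish grid — so the
real parsers are exercised. Degradation coarsens a configured fraction of
grid references to 10 km, blanks dates to year-only, shifts dates before
1970, and appends exact duplicates of untouched records; counts are
`round(rate · n)` exactly and a manifest lists every alteration, making
rejection counts predictable to the record.

What the generator does **not** emulate: spatial autocorrelation of
occupancy, observer-level heterogeneity, species interactions, phenology
(visit dates are uniform within the year), or real visit-intensity
trajectories. Passing recovery tests therefore demonstrates correctness
of the machinery under the model's own assumptions, not robustness to the
additional biases of real scheme data.

## Validation experiments

- **Enumeration oracle.** On a 2-site × 2-year instance with all
  continuous parameters fixed, the sampler's marginal P(z=1) and mean
  occupied proportion are compared with a from-first-principles sum over
  all 2^4 occupancy configurations, within 3 Monte-Carlo standard errors.
- **Simulation-based calibration.** 200 replicates at 20 sites × 10 years
  × 3 visits/site-year: parameters and data drawn from the prior
  predictive, the model refitted, and the rank of each true parameter
  among 19 spaced posterior draws tested for uniformity (chi-squared at
  1%). SBC runs with unit-scale priors (half-Cauchy scale 0.5) for both
  generator and model: calibration is a property of the sampler under any
  self-consistent prior, and the production vague scales saturate the
  logit scale at this instance size, which degrades the rank statistic
  numerically without testing anything additional.
- **Truth recovery.** Replicate mid-size datasets (150 sites in three GB
  countries, 46 years, ~0.5 visits/site-year, ~8–9 k records) are pushed
  through the full pipeline; 95% credible intervals are scored for
  coverage of the true `psi_fs` and the posterior mean for bias, averaged
  over region-years and replicates. Averaging over replicates (3 by
  default) separates systematic error from single-realisation Monte-Carlo
  spread; the coverage check widens the binomial standard error to the
  replicate-region cluster level because years within one region's
  trajectory are strongly correlated. Per-fit chains are 9,000 iterations
  (4,000 burn-in, thinning 5, 3 chains), sized so the three-replicate
  experiment completes in minutes on one CPU while keeping Rhat near 1.

## Known limitations

- The sampler is single-machine and per-species; very large schemes would
  want the per-species process parallelism the pipeline's seeding scheme
  (master seed + species-name hash) already makes order-independent.
- Metropolis year effects mix more slowly than a blocked or
  Pólya-Gamma-augmented sampler would; the defaults compensate with
  iterations.
- At sparse effort (around half a visit per site-year, the mid-size
  design's condition) the posterior systematically trades detection down
  for occupancy up: the recovery experiment measures a positive mean bias
  in `psi_fs` of a few hundredths alongside nominal interval coverage.
  This is a property of the model and priors at that effort level — an
  independent Gibbs-sampler engine fitted to the same data reproduces it —
  not of the sampler; it shrinks as per-site revisit rates grow.
  Single-replicate bias also carries realisation spread of similar
  magnitude, so conclusions about bias should average replicates.
- The continuous list-length variant, phenology terms, false-positive
  states, and multi-species indicator aggregation are intentionally out
  of scope.
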