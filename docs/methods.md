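# Methods

## The estimation problem

Survival studies of long-lived, hard-to-sample animals routinely end up
with two kinds of records for the same marked population: a designed
known-fate dataset (radiotelemetry, where every scheduled relocation
reveals alive/dead status) and a pile of incidental re-sightings of marked
individuals collected with no sampling design and unknowable effort.  The
incidental records cannot support capture-recapture models — there are no
occasions and no detection-probability structure — but they do carry one
piece of information both datasets share: the continuous time from first to
last sighting, and the fate at last sighting.  A continuous time-to-event
model can therefore pool them.

## Model

Each individual i belongs to one of eight groups j formed by crossing
residency (resident / translocated), age class (adult / juvenile, split at
180 mm midline carapace length) and study site (north / south).  Each
group has a constant weekly hazard

    lambda_j = exp(beta_j),     S_j(t) = exp(-lambda_j t),

with t in weeks.  An observed death at time t_i contributes the density
f(t_i) = lambda_j exp(-lambda_j t_i); an animal alive at its last
observation is right-censored and contributes only S(t_i).  The full
log-likelihood reduces to

    sum_j [ D_j beta_j - exp(beta_j) T_j ],

where D_j counts deaths and T_j totals exposure weeks in group j, so
(D_j, T_j) are sufficient.  Annual survival is S_j = exp(-52 lambda_j).
Because the exponential distribution is memoryless, each animal's clock
starts at its own entry (capture for residents, release for translocatees)
and staggered entry needs no left-truncation adjustment.

Groups are deliberately parameterized independently — one beta per
residency x age x site cell, no hierarchical pooling — so that large cells
cannot drag estimates for small cells.  Within-site comparisons use
contrast draws beta_j - beta_{resident adult, same site}; a contrast is
called significant when its equal-tailed 95% credible interval excludes
zero.  Cross-site contrasts are refused because site is confounded with
the local mortality environment.

## Data preparation

- Deaths are dated at the midpoint of the last-alive and first-dead
  observation dates.  For an odd day gap the midpoint is rounded toward
  the last-alive date, dating deaths conservatively early.
- Durations are fractional weeks (days / 7).  Rounding to whole weeks
  would discard information for no benefit in a continuous model.
- An individual whose first and last observations coincide carries zero
  elapsed time; it is excluded and counted, and retained + excluded always
  equals the input count.
- Censoring proportions (1 - deaths/individuals) are reported per
  monitoring-method x residency stratum; an empty stratum is flagged
  undefined rather than silently reported as 0 or 1.
- A mark-encounter death record must carry a first-dead date; the death is
  then dated by the same midpoint rule (with the marking date standing in
  when no live re-sighting exists).

## Priors and sampling

Default prior: beta_j ~ Normal(0, sd 10) on the log weekly-hazard scale,
which is vague over any biologically possible hazard.  A Gamma(a, b) prior
on lambda_j is also supported; it is conjugate to this likelihood
(posterior Gamma(a + D_j, b + T_j)) and exists mainly so the sampler can
be checked against an exact posterior.

The sampler is per-coordinate random-walk Metropolis.  The posterior
factorizes over coordinates (independent groups, independent priors), so
per-coordinate accept/reject steps vectorized across chains and groups are
exact.  Proposal scales adapt by Robbins-Monro recursion toward 0.44
acceptance during burn-in only; after burn-in the kernel is fixed, so
detailed balance holds for every retained draw.  The inner loop is
compiled with numba, with a pure-numpy reference implementation of
identical semantics as fallback.  Per-chain random substreams are spawned
deterministically from a single integer seed (Philox), so a fixed seed
gives bit-identical draws.

Desk-scale defaults: 3 chains x 20,000 iterations, 5,000 burn-in, thin 5
(9,000 retained draws, a few tenths of a second per fit).  Much longer
runs are a config change; memory stays bounded because proposals are
generated in blocks.  Convergence is judged by split-chain Gelman-Rubin
R-hat < 1.01 on every parameter (computed via ArviZ, as is the
autocorrelation-based effective sample size); a non-converged fit is
returned with a warning, and the command-line pipeline exits nonzero.

A group whose total exposure is below one animal-week is reported
*inestimable*: its posterior is prior-dominated and summaries print a dash
instead of numbers.  Point estimates are posterior medians by default
(survival posteriors near 1 are strongly skewed; the median is the more
robust center); means are available by argument.  Intervals are
equal-tailed 2.5%/97.5% quantiles, and the precision metric is the spread
(upper - lower) with percent decrease 100(1 - combined/radio-only),
rounded half-up to one decimal.

## Synthetic data generator

The generator emulates the sampling of a two-site tortoise translocation
program; its defaults are the study's conditions:

- **Cohorts.** 153 translocatees released in four cohorts (110 in early
  October 2014, 22 in April 2015, 3 in October 2016, 18 in September
  2017); 68 residents captured on a rolling basis March 2013 - December
  2015.  Per-group counts by monitoring method follow the study's
  sample-size table (139 radio, 82 mark-encounter).  Study end is
  30 April 2018.
- **Mortality.** True weekly hazards default to the values implied by the
  study's reported annual survival (0.732-0.998 across groups).  An
  optional calendar-window pulse multiplies the hazard (piecewise-
  exponential times by inverse-CDF), for probing the constant-hazard
  assumption against episodes like a localized predation spike.
- **Radiotelemetry.** Relocations every 7 days March-October; every 28
  days (adults) or 14 days (juveniles) November-February.  last-alive /
  first-dead bracket the true death date, so midpoint dating error is
  bounded by the cadence.
- **Incidental encounters.** Effort is unknowable in real incidental data;
  it is modeled as a per-animal homogeneous Poisson sighting process with
  lognormal rate across animals (median 0.03/week, sigma 1.0 — most
  animals re-sighted a handful of times over several years, a minority
  never, echoing the huge single-sighting attrition of real incidental
  datasets).  A death is recovered with probability `p_dead_found` after
  an exponential discovery lag (mean 2 weeks); default `p_dead_found` is
  0.2, reproducing the sparse dead recovery of incidental monitoring.
  Setting it to 1.0 makes censoring unrelated to mortality ("random
  censoring"); setting it to 0 is the worst-case detection failure.

What the generator does **not** emulate: spatial structure and movement,
per-survey effort footprints (the Poisson-with-heterogeneity process is an
assumption, not a reconstruction of occupancy/line-distance crews),
individual covariates beyond the three grouping factors, and
disease/body-condition processes.  Passing tests therefore demonstrate
correctness of the estimator under the stated sampling model, not
robustness to every field reality.

## What the simulation study shows

With dead recovery unrelated to method (`p_dead_found = 1`), combined
point estimates track radio-only ones (mean difference indistinguishable
from zero) and 95% intervals cover the true hazard at the nominal rate;
mean interval spread shrinks in every group.  With mark-encounter deaths
never recovered (`p_dead_found = 0`), the combined fit overestimates
survival (positive mean point difference and positive bias against truth)
— animals that died are censored at their last sighting, which is
informative censoring.  The study-like default (0.2) sits between the two,
which is exactly the caution the approach carries for real incidental
data: the precision gain is real, but dead-detection failure specific to
the incidental stream buys precision at the price of upward bias.

Problem sizes used by the shipped analyses and acceptance checks: 200
replicates for interval coverage, 60 per bias scenario (the per-replicate
point-difference distribution is heavy-tailed because one group has a
single radio animal, so bias scenarios use more replicates than the
precision check), 20 for the precision-gain summary, with the short MCMC
(2 chains x 4,000 iterations, burn-in 1,500, thin 2) whose R-hat and
oracle checks pass at the same settings.

## Numerical details and edge cases

- Non-finite coefficients get log-likelihood -inf (rejectable) rather
  than an exception, so proposal wildness cannot crash a chain.
- `D_j = 0` makes the hazard MLE 0; it is flagged degenerate.  `T_j = 0`
  is flagged inestimable.  The conjugate oracle with no data returns the
  prior.
- R-hat and ESS on constant chains are undefined and flagged (NaN), never
  silently 1.
- The interchange formats are plain CSV with ISO-8601 dates; time-to-event
  durations round-trip bit-exactly (written via `repr`).
- Percent decreases are rounded half-up (not banker's rounding) to one
  decimal for report parity.

## Known limitations

The constant-hazard assumption averages over any within-study temporal
structure; under a mortality pulse the fitted lambda is an
exposure-weighted average, and interval-specific survival would differ.
The generator's discovery-lag and encounter-rate defaults are plausible
rather than estimated.  Radio-only fits of near-empty groups are
prior-influenced even when they pass the one-animal-week estimability
bar; their summaries are wide and their point estimates should not be
over-read.
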