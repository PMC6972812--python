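# incsurv

Survival estimation that pools a designed known-fate dataset
(radiotelemetry) with incidental re-sightings of marked animals, using a
Bayesian exponential time-to-event model with right-censoring.  Built
around a two-site Mojave desert tortoise (*Gopherus agassizii*)
translocation study, but the machinery — time-to-event construction,
constant-hazard MCMC, precision comparison, synthetic-data generation — is
generic for any marked population with the same two data streams.

## The idea

Incidental sightings of marked animals have no occasions, no effort data
and unknowable detection probability, so they cannot feed
capture-recapture models.  But they share one piece of information with a
telemetry dataset: the continuous time from first to last sighting, and
the fate at last sighting.  Under a constant weekly hazard
λ_j = exp(β_j) per demographic group j (residency × age class × site),

- a death at t contributes f(t) = λ e^{-λt},
- an animal alive at last sighting contributes S(t) = e^{-λt} only,

and the log-likelihood collapses to Σ_j (D_j β_j − e^{β_j} T_j) with D_j
deaths and T_j exposure-weeks per group.  Annual survival is
S_j = e^{-52 λ_j}.  Pooling the incidental records adds exposure (and the
odd recovered death) to every group, narrowing credible intervals and
rescuing groups that have no telemetry at all — at the price of bias *if*
dead animals selectively vanish from the incidental stream, which the
included simulation study quantifies.

## Layout

- `src/incsurv/` — the library: encounter records and validation
  (`records`), time-to-event construction and bookkeeping (`tte`),
  published reference tables (`eldorado`), likelihood/sampler/diagnostics
  (`model`), annual-survival summaries and contrasts (`summaries`),
  synthetic data (`simulate`), orchestration (`pipeline`), CLI (`cli`).
- `analysis/01…04_*.py` — numbered drivers: study bookkeeping, data
  generation, the radio-only vs. combined comparison, and the replicate
  simulation study.  Each writes its tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers end to end.

## Worked example

```python
from incsurv import SimulationConfig, generate_dataset, run_compare

cfg = SimulationConfig()                      # study-like conditions
records, truth = generate_dataset(cfg, seed=3)
res = run_compare(records, cfg.study_end, seed=11)
print(res.report.render_text())
```

```
group                        estimate          95% CrI radio sprd comb sprd  % decr  pt diff
resident.adult.north            0.976   (0.937, 0.994)      0.064     0.057    10.7   -0.003
resident.adult.south            1.000   (0.985, 1.000)          -     0.015       -        -
resident.juvenile.north         0.999   (0.885, 1.000)          -     0.115       -        -
resident.juvenile.south         1.000   (0.948, 1.000)      0.228     0.052    77.4   +0.001
translocated.adult.north        0.786   (0.719, 0.844)      0.134     0.125     6.6   +0.016
translocated.adult.south        0.964   (0.918, 0.989)      0.109     0.071    35.0   +0.001
translocated.juvenile.north     0.670   (0.517, 0.805)      0.290     0.288     0.7   +0.004
translocated.juvenile.south     0.730   (0.607, 0.834)      0.239     0.227     4.7   +0.008
```

Each row is one residency × age × site group.  `estimate` is the
posterior-median annual survival from the combined fit with its 95%
equal-tailed credible interval; the two spread columns are the interval
widths from the radio-only and combined fits; `% decr` is the precision
gain 100(1 − combined/radio); `pt diff` is the signed change in the point
estimate.  Dashes mark groups with no usable radiotelemetry exposure —
estimable only because the incidental data were added.  Point differences
hover near zero (no induced bias under the generator's conditions) while
every group's interval narrows.

The same pipeline is available from a shell:

```
incsurv simulate --out sim --seed 3
incsurv compare sim/encounters.csv --study-end 2018-04-30 --out fit --seed 11
```

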