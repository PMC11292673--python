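# predsupp

Simulation and hierarchical Bayesian analysis of auditory oddball fMRI:
predictive suppression along the auditory pathway, directional path models,
and 3AFC signal detection.

## The problem

When a rare deviant tone interrupts a stream of repeated standards, the
brain's response to it shrinks as its occurrence becomes more predictable.
In the paradigm this package models, the deviant appears at position 4, 5
or 6 of an 8-tone sequence, so its conditional probability rises along the
sequence (P = 1/3, 1/2, 1) — and the BOLD response in auditory regions
(inferior colliculus IC, medial geniculate body MGB, auditory cortex AC,
superior temporal gyrus STG) is expected to fall accordingly.  The
scientific questions are (i) whether this *predictive suppression* is
measurable per region, (ii) whether the cross-region dynamics are better
explained by top-down or bottom-up information flow, and (iii) whether
listeners can actually report the deviant's position (their sensitivity d').

`predsupp` is for researchers who want a fully seeded, testable version of
this analysis chain: simulate the experiment, estimate condition responses,
pool them hierarchically, compare directional path models, and model the
behavior — all from one seed, with every posterior draw reproducible.

## What's inside

* **Design & simulation** (`predsupp.design`, `predsupp.simulate`) — seeded
  oddball designs with exact counts (18 deviants per position and 21 silent
  trials per run), truncated-exponential ITI jitter, BOLD forward simulation
  with HRF convolution + AR(1) noise, and 3AFC behavior from a subject-level
  d' distribution.
* **First level** (`predsupp.glm`) — event-related design matrices
  (6 conditions + 2 position modulators, or 3 periodicity conditions),
  OLS with AR(1) prewhitening, per-run and pooled estimates with SEs.
* **Bayesian engine** (`predsupp.bayes`) — an in-package NUTS sampler with
  analytic gradients (6 chains × 2,000 iterations, zero-initialized), plus
  MAP, HDI95, probability of direction (p = 2(1−PD)), Savage–Dickey BF10,
  split-R-hat, and WAIC with difference SEs.
* **Second level** (`predsupp.second_level`) — multivariate multilevel
  measurement-error model over the four ROIs:
  `beta_obs ~ N(mu[roi,cond] + u[subj,roi] + eps, se_obs)` with
  `eps ~ MVN(0, diag(sigma) R diag(sigma))`, `R ~ LKJ(2)`; expectancy
  contrasts (std0−std1, dev4−std1, dev4−dev6, dev6−std2) and ROI–ROI
  correlations.
* **Path models** (`predsupp.paths`) — latent-score chain regressions with
  known observation SDs; bottom-up vs top-down vs intercept-only, compared
  by WAIC with the |ΔWAIC| > SE rule.
* **SDT** (`predsupp.sdt`) — hierarchical 3AFC model
  `k_s ~ Binomial(n_s, Pc(d'_s))`, `Pc(d') = ∫ φ(x−d') Φ(x)² dx`.
* **CLI** (`predsupp` command) — `simulate`, `fit-first-level`,
  `fit-second-level`, `fit-sdt`, `fit-paths`, `run-all`, `validate`.

Each analysis follows the Model/Results pattern: construct a model from a
data frame, call `.fit(seed=...)`, and read summaries off the results
object.

## Worked example

```python
import predsupp as pp

# a full seeded session for one subject
design = pp.generate_experiment(seed=1)
print(pp.deviant_hazard(design))          # {4: 0.333..., 5: 0.5, 6: 1.0}

truth = pp.default_ground_truth()          # expectancy amplitude profile
bold, nuisance = pp.simulate_experiment_bold(design, truth, seed=2)
estimates = pp.fit_first_level(design, bold, nuisance, subject=0)

# behavioral arm: 10 subjects at group d' = 3.38
behavior = pp.simulate_behavior(design, truth, n_subjects=10, seed=3)
sdt = pp.SDTModel(behavior).fit(seed=4)
print(sdt.group_summary())
```

Running exactly this prints (seeds as shown):

```
{4: 0.3333333333333333, 5: 0.5, 6: 1.0}
FitSummary(name='mu_dprime', map=3.2017865077415895,
           hdi_lower=2.880651370454227, hdi_upper=3.635378436240174,
           pd=1.0, p=0.0, bf10=inf, rhat=1.0017019732830916)
```

The hazard is exact by construction; the fitted group sensitivity (MAP
3.20, HDI95 [2.88, 3.64]) recovers the generative d' = 3.38 within its
interval, and PD = 1 (p = 0) says the posterior puts all its mass above
zero — the simulated listeners clearly identify the deviant position (the
infinite Bayes factor is the Savage-Dickey ratio degenerating when the
posterior leaves no density at zero).  A pooled second-level
fit of several such subjects (see `predsupp run-all`) yields the
expectancy contrasts: with the default amplitude profile, predictive
suppression (dev4−dev6) is strongly positive in AC and IC and weak in STG
(PD = 1 in AC and IC), and in the suppression path analysis both
directional models — which carry the deviant-position effect — beat the
intercept-only model by a WAIC margin of roughly five standard errors.

## Layout

```
src/predsupp/        library (design, simulate, glm, bayes/, second_level,
                     sdt, paths, pipeline, cli, io)
tests/               pytest suite incl. end-to-end acceptance checks
scripts/acceptance.py
docs/methods.md      modeling choices, assumptions, limitations
```
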