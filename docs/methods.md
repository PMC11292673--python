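# Methods

This note documents the models implemented in `predsupp`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## The paradigm being modeled

An auditory oddball session consists of 4 runs, each with 6 blocks of 9
tone-sequence trials (54 tone trials per run) plus 21 interleaved silent
trials.  A trial is a sequence of 8 tones (250 ms tones, 700 ms
offset-to-onset gap, i.e. 950 ms onset asynchrony) in which a single deviant
tone occurs at position 4, 5 or 6, exactly 18 times each per run.  Because
the deviant must occur at one of the three positions, its conditional
probability rises along the sequence: 1/3 at position 4, 1/2 at position 5
given it has not occurred, and 1 at position 6.  These values are exact by
construction in every generated run, and the generator's invariants enforce
them.  Inter-trial intervals are jittered on [1.5, 11] s with mean 5 s.

Tone events are labeled std0 (first tone of a sequence), std1 (standards
before the deviant), dev4/dev5/dev6 (the deviant by position), and std2
(standards after the deviant).  An orthogonal periodicity manipulation
assigns each run's 6 blocks evenly (2/2/2) to control / inphase / antiphase
conditions.

Regions of interest are the ascending auditory pathway: inferior colliculus
(IC), medial geniculate body (MGB), auditory cortex (AC), and superior
temporal gyrus (STG).

## Design generator choices

* **ITI jitter law.** Only the bounds (1.5–11 s) and mean (5 s) of the
  jitter are fixed by the paradigm; the distribution is our choice.  We use
  a truncated exponential with its rate solved numerically so the truncated
  mean is exactly 5 s, sampled by inverse CDF.  An exponential-family jitter
  is the standard efficiency-oriented choice for event-related designs and
  honors both constraints simultaneously.
* **Inter-tone timing.** "700 ms inter-stimulus interval" is read as
  offset-to-onset, giving a 950 ms onset asynchrony; configurable.
* **Events are sticks.** Tones are modeled as zero-duration impulses rather
  than 250 ms boxcars; at a TR of 1.53 s the difference is a constant scale
  factor absorbed by the amplitudes.
* **Run length** is emergent: volumes = ceil((last event onset + 32 s)/TR).
* Button presses are not modeled in the BOLD forward model, and motion
  nuisance regressors are smoothed seeded random walks (placeholders with
  zero true weight by default, so the noiseless round trip is exact).

## BOLD forward model and first-level GLM

The forward model and the GLM share one code path: condition sticks on a
50 ms grid are convolved with a canonical double-gamma HRF (gamma modes at
6 s and 16 s, undershoot ratio 1/6, peak scaled to 1) and sampled at volume
times.  Parametric modulators for std1 and std2 carry the ordinal
within-sequence position, mean-centered per run, on the same sticks.  The
model adds a discrete-cosine drift set (1/128 Hz cutoff), six nuisance
columns, and an intercept.  Noise is AR(1) (default rho = 0.3, innovation SD
6 in amplitude units) plus random cosine drift.

Fitting is OLS with optional AR(1) prewhitening (rho estimated from OLS
residuals, Cochrane–Orcutt transform with exact scaling of the first
sample, then refit).  Each subject yields per-run condition estimates with
standard errors, plus inverse-variance-pooled per-subject rows.  Because
the generator and the GLM share the forward model, a noiseless simulation
is recovered to machine precision — the round-trip identity that anchors
the unit tests.

The default ground-truth amplitude profile follows the expected expectancy
pattern: strong std0 response, adapted std1/std2, deviant response
decreasing over dev4 → dev5 → dev6 in IC, MGB and AC (monotonicity is
enforced for these "suppressive" regions), a flat deviant profile in STG,
and cortical effects roughly 4× the subcortical ones.  These are generator
settings, not analysis targets.

## Posterior computation

No probabilistic-programming backend is used: the package ships its own
No-U-Turn sampler (recursive slice variant, max tree depth 10, divergence
threshold 1000 on the energy error) with dual-averaging step-size
adaptation (target acceptance 0.8) and three expanding diagonal
mass-matrix adaptation windows inside the warmup.  Every model provides an
analytic gradient of its joint log density; all gradients are verified
against finite differences in the test suite.  The sampling contract is 6
chains × 2,000 iterations, first 1,000 discarded, no thinning, chains
initialized at zero in the unconstrained space.  Split-R-hat above 1.01 on
any parameter attaches a convergence warning to the result.

Positive scales are sampled on the log axis.  Correlation matrices use the
C-vine construction of the LKJ distribution: tanh-transformed unconstrained
parameters are canonical partial correlations with Beta(b, b) marginals,
b = eta + (K − 2 − j)/2 for conditioning-set size j, which induces exactly
LKJ(eta) on the assembled matrix; gradients flow through the Cholesky
construction by forward-mode tangents.  This construction was chosen
because the induced prior on the unconstrained scale is available in closed
form (no Jacobian bookkeeping) and is verifiable by simulation — the test
suite checks the off-diagonal moments against the known LKJ marginals.

Inference summaries follow one convention everywhere: MAP is the peak of a
Silverman-bandwidth Gaussian KDE on a 512-point grid; HDI95 is the shortest
contiguous interval holding 95% of the draws; the probability of direction
PD is the posterior mass on the dominant sign, converted to a two-sided
p-value as p = 2(1 − PD); BF10 is the Savage–Dickey density ratio
prior(0)/posterior(0) with KDE densities.  WAIC is −2(lppd − p_waic) with
the log-sum-exp lppd and the summed posterior variance penalty; the SE of a
WAIC difference is 2·sqrt(n·Var(elpd_i differences)).

## Second-level model

First-level betas are noisy measurements with *known* SDs:

    beta_obs ~ Normal(eta, se_obs)
    eta[cell, roi] = mu[roi, cond] + u[subject, roi] + eps[cell, roi]
    u[subject, roi] ~ Normal(0, tau[roi])
    eps[cell, ·] ~ MVN(0, diag(sigma) R diag(sigma))

with one cell per subject × run × condition.  The cross-ROI coupling sits
on the cell-level residual eps (not on u), which is what produces the
reported ROI–ROI correlations.  Priors are weakly informative and
scale-adaptive: mu ~ Normal(0, 10·sd(beta)), tau and sigma half-t(3)
scaled to sd(beta), R ~ LKJ(2).  Both random effects and residuals are
non-centered for the sampler.  Default granularity is per-run rows (more
observations for the path models); a switch selects subject-pooled rows.

Contrasts are computed per posterior draw: adaptation (std0−std1), deviant
detection (dev4−std1), predictive suppression (dev4−dev6), complete
suppression (dev6−std2); for the periodicity arm, inphase−control,
antiphase−control, inphase−antiphase.  The contrast BF10 uses prior draws
of the implied contrast (difference of two independent mu priors).  WAIC
uses the conditional (given latent quantities) pointwise likelihood on the
observation layer — the common choice for multilevel models; the marginal
variant would require analytic integration that the chain structure of the
path models does not share.

## 3AFC signal-detection model

Per-subject correct counts are binomial with the unbiased-observer link

    Pc(d') = ∫ φ(x − d') Φ(x)² dx,   k_s ~ Binomial(n_s, Pc(d'_s)),
    d'_s ~ Normal(mu_d', sigma_d')

with priors mu_d' ~ Normal(0, 3) and sigma_d' ~ half-normal(1.5): wide
enough for an easy task, without forcing the group mean positive.  The
public link uses adaptive quadrature (absolute error well under 1e−8); the
sampler uses a 64-node Gauss–Hermite version with an analytic derivative.
The three response alternatives are exchangeable — deviant position is not
a spatial interval with a classical bias structure — so no bias parameters
are fitted; per-position accuracy is exported descriptively.  Floor and
ceiling subjects are retained; the hierarchy regularizes them.

The subject sensitivities are sampled in the *centered* parameterization
(d'_s directly, not as scaled offsets): with hundreds of trials per
subject the likelihood pins each d'_s tightly, and in that strong-data
regime the non-centered variant produces a curved ridge between the group
parameters and the subject offsets that the sampler traverses poorly.  The
multilevel imaging models keep the non-centered form, where the per-cell
information is weaker.

## Path models

Two analyses compare a bottom-up chain, its top-down mirror, and an
intercept-only null by WAIC:

* **detection** — std0 responses in all four ROIs, raw scale;
  bottom-up IC→MGB→AC→STG, top-down STG→AC→MGB→IC.
* **suppression** — deviant responses in the ROIs showing suppression
  (IC, MGB, AC), z-scored per subject × ROI (SEs divided by the same sd),
  deviant position coded 1/2/3 as an exogenous error-free source, and
  participant random intercepts; top-down position→AC→MGB→IC, bottom-up
  position→IC→MGB→AC.

Each node's observed beta measures a latent score (b ~ Normal(t, se)); the
structural layer regresses each latent on its parent's latent, so
first-level uncertainty propagates on both sides of every edge.  Position
coding 1/2/3 affects only intercepts, not slopes.  Priors: alpha, beta ~
Normal(0, 5) on the standardized scale (Normal(0, 10·sd) otherwise),
structural scales half-t(3).  A comparison declares a winner only when its
|WAIC difference| exceeds the SE against every competitor, and a
"directional" verdict additionally requires both directional models to beat
the null.

Internally the sampler works in an affine reparameterization (structural
regressors centered on the parent's mean, latents and coefficients
preconditioned by node SDs).  This is a fixed linear change of variables —
likelihood, priors and WAIC are mathematically unchanged — that removes the
severe intercept/slope posterior correlation raw-scale chains otherwise
exhibit.  The reported alpha is therefore the centered intercept (expected
score at the parent's mean).

### A structural identifiability limit

Reversing a linear-Gaussian chain with free intercepts yields a
Markov-equivalent model: both directions parameterize exactly the same
family of joint Gaussian distributions, so for data that truly come from
such a chain, WAIC cannot systematically prefer the generative direction —
differences reflect only the latent-penalty geometry and Monte-Carlo noise.
This applies to the detection analysis, whose two chains differ only in
orientation.  The suppression analysis does not suffer from this: the
exogenous position source breaks the reversal symmetry (position is
error-free and enters only one end of the chain), and simulation shows
large, stable WAIC margins for the generative direction there.  Directional
conclusions for the detection analysis on real data therefore lean on
departures from the Gaussian-chain family (non-Gaussianity,
heteroscedasticity, unmodeled clustering) rather than on the chain
structure itself — a caveat worth carrying when interpreting such results.

## Problem sizes used by the tests and the acceptance script

Replicate sweeps (calibration, coverage, model selection) run the sampler
at 1–2 chains with 500–1,000 retained draws, and the simulated imaging arm
uses 6 subjects × 1–2 runs; the behavioral arm keeps the full 10 subjects ×
216 trials.  These sizes are the package's own trade-off between
Monte-Carlo resolution and turnaround; the full 6 × 2,000 contract and the
full 4-run design remain the defaults for real use and are exercised
directly by the engine tests and the pipeline defaults.

## Known limitations

* The noise model is AR(1) + cosine drift; physiological noise, motion
  spikes and multiband artifacts are out of scope.
* The BOLD generator shares its forward model with the GLM, so GLM tests
  validate internal consistency, not robustness to HRF misspecification.
* Conditional-likelihood WAIC penalizes latent-variable models through the
  per-observation latent fit; absolute WAIC values are therefore not
  comparable across packages that use the marginal likelihood.
* The mAFC link assumes an unbiased observer and exchangeable positions.
* KDE-based MAP and Savage–Dickey estimates inherit kernel-bandwidth bias;
  BF10 values far above ~10^3 are effectively "posterior mass nowhere near
  zero" statements, not precise ratios.
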