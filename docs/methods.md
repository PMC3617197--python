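# Methods

## The task and the quantity of interest

In the gap paradigm a participant commits to initiating a left/right
choice response *before* the discriminative stimulus is shown: a go
signal triggers a key press, and the target appears only after a random
*gap* (uniform, 0–330 ms) measured from that key press.  Short gaps
make the response stimulus-driven; long gaps force a pure guess.  The
central observable is the **raw processing time**, rPT = RT − gap: how
long target information was available before the choice response
(negative when the response preceded target onset).  Accuracy as a
function of rPT — the **tachometric curve** — is flat at chance below a
critical rPT and rises toward ceiling above it.

## The hybrid two-stage race model

Two evidence variables race to a common response threshold
Θ_R = 1000 (arbitrary units; every other parameter is scaled to it):

* the **internal** variable starts at the key press (t = 0) with slope
  r_I and codes a side drawn as a fair coin (or with probability α for
  the cued side in the biased design);
* the **external** variable starts at target onset (t = gap) with slope
  r_E and always codes the correct side.

Rates are drawn per trial from lognormal distributions,
ln r_I ~ N(μ_I, σ_I²) and ln r_E ~ N(μ_E, σ_E²), and stay constant
within a trial except for the interaction below.  There is no
within-trial diffusion noise and no afferent delay, so trajectories are
deterministic given the draws and every event time has a closed
piecewise linear/quadratic form (the implementation is fully
vectorized; a fine-grid Euler integrator in the test suite serves as an
independent oracle, agreement ≤ 0.05 ms).

**Two stages.**  Until *both* variables exceed the transition threshold
θ (0 < θ < Θ_R) they accumulate independently.  From that moment
(t_trans) the external variable drives the internal one: the internal
slope moves from r_I to r_I + r_E when both code the same side
(*congruent* — facilitation) or to r_I − r_E otherwise (*incongruent* —
inhibition, possibly to a negative slope with no floor and no
re-labelling).  The interaction parameter A (ms) is the time the
external influence needs to take full effect.  The first variable to
reach Θ_R sets the response side; its crossing time plus the execution
delay t_exec is the RT.  Consequences worth noting:

* congruent trials are always correct; every error is incongruent or a
  pre-target guess;
* when the response-threshold crossing precedes the external variable's
  θ-crossing, target information never entered the race; such trials
  are labelled `internal_only` (pure guesses, chance accuracy);
* when the external variable reaches Θ_R before the internal has
  crossed θ, the trial is purely stimulus-driven.

**Ramp form.**  The published description of the model specifies a
smooth differential-equation transition whose exact form is not fully
determined.  The default here is a linear ramp completing in exactly A ms
(matching "time needed to fully influence"); an exponential relaxation
with time constant A is selectable (`ramp="exponential"`) for
sensitivity checks.  Both agree in the A → 0 and A → ∞ limits
(instantaneous switch and independent race, respectively).

**Ties and divergence.**  Simultaneous Θ_R crossings (measure zero) are
resolved by the trial's seeded RNG.  Trials in which no variable
reaches Θ_R within 5000 ms raise an error by default; during likelihood
evaluation — where the optimizer explores parameter regions that
produce such trials — they are instead censored to RT = +∞, which
places them outside every observed histogram cell and lets the
multinomial likelihood penalize them.  They are never silently dropped.

## Comparison models

All models share the trial contract (same outcome schema,
rPT = RT − gap):

* **independent race** (5 parameters): the hybrid race without the
  interaction; the hybrid model converges to it as A → ∞.
* **single-race alternative** ("stanford_simplified", 8 parameters): a
  left and a right motor variable build up from the key press with
  correlated lognormal rates; after target onset plus an afferent delay
  the target-side variable's rate is incremented and the
  distractor-side rate decremented (linear ramp).  The original
  parameterization of this simplified variant was not available; ours
  is a reconstruction honoring the printed 8-parameter count
  (build-rate μ/σ, accel, decel, afferent delay, execution delay, ramp
  duration, rate correlation), declared in configuration rather than
  hard-coded.
* **drift diffusion** (4 parameters) and **Ornstein–Uhlenbeck**
  (5): a single process between bounds ±1000; pre-target drift ±v_int
  with random sign (the internal decision), post-target drift +v_ext
  toward the correct bound; Euler–Maruyama at 1 ms, seeded; the OU leak
  λ = 0 reduces exactly to the DDM.  For these two, within-trial noise
  means a congruent trial can still end at the wrong bound, so the
  "congruent ⇒ correct" guarantee applies only to the three ballistic
  race models.

## Simulated maximum likelihood

Per subject, trials enter as a joint histogram of rPT (35 ms bins,
aligned to zero, spanning the observed range) by correctness.  For a
candidate parameter vector the model is simulated (default 2×10⁴
trials per evaluation; gaps resampled with replacement from the
subject's own gaps) and the smoothed cell frequencies (pseudo-count 0.5
per cell) define a multinomial log-likelihood.  Simulated mass outside
the observed range stays in the normalizer, penalizing parameters that
push responses off the observed support.  A pooled-correctness variant
is available by flag.

One set of base random draws is reused for every evaluation (common
random numbers), making the surface deterministic and smooth in the
parameters for a fixed seed.  Optimization is Nelder–Mead over
transformed parameters (log for scales and delays, logit of θ/Θ_R,
logit for α, atanh for correlations) from Latin-hypercube multi-starts
(default 8).  Because the coarse surface is piecewise constant (cell
counts move in quanta of 1/n_sim), the best restart endpoints are then
re-polished with fresh simplexes at 5× the simulation size.  AIC and
BIC use the standard forms 2p − 2logL and p ln n − 2logL with n the
number of observed trials.

**Identifiability.**  σ_I, σ_E and A are weakly identified at realistic
trial counts.  At 600 trials per subject the binned likelihood also has
near-flat plateaus along which θ, the rate locations and t_exec trade
off; independently evaluated likelihoods at fitted points match or
exceed those at the generating parameters, so fits recover the MLE —
but the MLE itself can sit 20–30% away from the generating θ.  Recovery
tests should be read with that in mind.

## Group-level model selection

Per-subject evidence is approximated by −AIC/2 or −BIC/2.  Model
identity is a random effect across subjects with population frequencies
r ~ Dirichlet(1, …, 1); a variational update iterates posterior
assignments and Dirichlet counts to convergence (tolerance 1e-6).  The
exceedance probability of model k — the posterior probability that r_k
is the largest — is estimated from 10⁶ Dirichlet samples (seeded).  A
Gibbs sampler in the test suite cross-checks the variational posterior.

## Behavioral analyses

* **Outlier pass**: trials with |RT − mean| > 4 SD removed, single
  pass, per subject, before any other analysis.
* **Tachometric curve**: per-bin accuracy (35 ms), low-count bins
  flagged.
* **Critical rPT**: 4-parameter sigmoid (floor, ceiling, center, width)
  fit to trial-level correctness by Bernoulli maximum likelihood; the
  critical value is the fitted center, its SE a nonparametric bootstrap
  over trials (default 1000 resamples).  A piecewise
  chance/ramp/ceiling fit is available (`shape="piecewise"`; it reports
  the ramp midpoint so both shapes return the half-rise point).  The
  center of a sigmoid fitted to a slowly saturating curve sits well
  above the point where accuracy first leaves chance; see the
  limitations below.
* **RT-on-gap slope**: per-subject OLS with 95% CI.  Slopes below 1
  indicate participants did not simply wait out the gap.
* **Congruency deconvolution** (biased design): conditional on the
  target appearing on the cued side, a trial is congruent with
  probability α, so the per-side rPT densities are mixtures
  [M; L] = [[α, 1−α], [1−α, α]] [C; I], inverted bin-wise (singular at
  α = 0.5, which is why the unbiased design cannot separate the
  classes).  The mixture weights are exact when the per-side densities
  include **all** trials; restricting to correct trials skews the
  weights because incongruent trials are not always correct (validated
  against latent labels: total-variation error at the sampling-noise
  level for all-trials inputs, up to ~0.4 for correct-only inputs).
  Error trials are necessarily incongruent and pass through unchanged.
  Negative cells from sampling noise are reported and flagged below
  −0.02, with optional clipping.
* **Peak locations** of binned densities use a quadratic through the
  maximal bin and its neighbours to resolve sub-bin shifts.

## Synthetic experiments

The generator emulates the study design: gaps uniform on 0–330 ms from
the key press; target side 50/50, or 65/35 conditional on a balanced
binary cue with the cue-to-side assignment counterbalanced across
subject halves; default 540 trials per subject (per-subject totals for the
original studies are not published; configurable).  The reference
per-subject parameter tables (10 unbiased-study subjects, 11
biased-study subjects with fitted α) ship with the package and are the
default generating parameters.  The 850 ms response deadline and
20-trial feedback blocks are recorded as metadata only: the model has
no feedback-adaptation mechanism, so they do not alter generation.
What the generator does **not** emulate: sequential effects and
learning, the response deadline's truncation of slow trials, motor
variability beyond the execution delay, and any stimulus-level
properties.  Passing tests therefore certify the internal consistency
of model, fitter and analyses — not that real data were collected this
way.

## Problem sizes and seeds

The shipped reproduction script simulates 2×10⁴ trials per subject for
the unbiased-study summaries, 5×10⁴ for the biased-study densities, and
uses 6 subjects × 400 trials with reduced fitting settings (10⁴
simulations per evaluation, 4 restarts) for the model-recovery
comparison — sizes at which every quantity is stable to well within its
reported tolerance on a single CPU.  All randomness flows from one
`--seed` argument through `numpy.random.Generator`.

## Known limitations

* The exact transition differential equation and the original
  parameterizations of the simplified single-race/DDM/OU variants are
  reconstructions (flagged above); all are configurable.
* The sigmoid-center critical rPT on data simulated from the reference
  parameters lands near 250 ms: the simulated tachometric curve
  saturates more slowly than the sharp transition reported for real
  behavioral data around 202 ms, because slow-external subjects
  keep producing incongruent errors at moderate rPTs.  The breakpoint
  (chance-departure) reading of the critical value, available via the
  piecewise fit, sits near 190–200 ms.
* Parameter recovery at a few hundred trials is limited by likelihood
  plateaus (above), not by the optimizer.
* Likelihoods are simulation-based throughout; no closed-form
  first-passage densities are used for the diffusion models.
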