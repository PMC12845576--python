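# Methods

## Model

`dyadinfer` models one participant in a dyadic category-judgment task as an
active-inference agent over binary actions (touch / no touch). Two belief
layers track the partner's touch probability conditioned on the agent's own
action:

* the **single-Bayes** layer is a pair of Beta–Bernoulli posteriors, one per
  self-action condition, updated by unit pseudo-count increments from the
  observed action pair of each trial. Its point estimate is the posterior
  mean — conjugate, well defined at the uniform prior, and identical to a
  smoothed relative frequency;
* the **double-Bayes** layer is an exponential moving average of observed
  partner actions per self-action condition, updated only on trials whose
  self action matches the condition. It reacts faster than the counting
  layer and represents the agent's refined, recency-weighted expectation.

The per-action free energy is the compressed KL divergence between the two
layers, `kappa * D/(1+D)`, plus an agreement/risk term
`lambda0 * gamma_t * (2q - 1)`. The compression maps the unbounded KL into
`[0, kappa)` so neither term dominates; the agreement term is negative when
the partner is expected not to touch and positive when a touch is expected,
so minimizing G steers the agent toward actions whose anticipated partner
response it has learned to expect. The functional form is implemented
literally; whether the sign semantics are best read as "risk" or as
"agreement seeking" is an interpretive question the implementation does not
resolve. Action selection is a deterministic argmin; the softmax over
`-G/tau` is reported for evaluation only.

Two modelling points were genuinely open and are fixed here as package
design choices:

* **Prediction layer and ordering.** The per-trial partner prediction
  `P(A_p = 1)` is the single-Bayes posterior mean conditioned on the
  *predicted* (argmin-G) self action, computed from beliefs accumulated over
  trials 1..t-1 only; the trial's own outcome is applied afterwards. The
  counting layer is the direct partner-behavior predictor; the EMA layer
  enters through the free energy.
* **Conditioning.** Beliefs are conditioned on the self action only, not on
  object identity; a per-object belief table would need far more trials than
  a 24-trial session provides.
* **Ties and absences.** Exact free-energy ties resolve to "no touch"
  (configurable via `ModelConfig.tie_break`); trials without gaze data get
  `gamma_t = 0`, disabling the agreement term for that trial only; trials
  where nobody touched contribute `a_p = 0` to both layers, i.e. "did not
  touch" and "no observation" are not distinguished.

Defaults (`ModelConfig`): `kappa = 0.1`, `lambda0 = 1.0`, `tau = 1.0`,
`ema_alpha = 0.8`, Beta priors `(1, 1)`, `q_init = 0.5` (matching the
uniform-prior mean so both layers start maximally uncertain),
`epsilon = 1e-12`. These are fixed constants of the model, not fitted; only
the base synchrony weight `gamma0` is swept, over `{0, 0.1, 0.5, 0.9}`.

## Gaze synchrony

Paired pupil-position streams (3-D, nominally 80 Hz, variable rate) are
cleaned of missing samples, linearly resampled onto a shared 0.02 s grid
over their temporal overlap, and differenced into per-axis velocities.
DTW uses the conventional definition — absolute-difference local cost,
steps (i-1,j), (i,j-1), (i-1,j-1), boundary-anchored, no window — because
no variant is singled out by the synchrony literature the pipeline follows;
it is computed per axis and averaged into one per-trial distance. (The
DTW dynamic program is implemented in-package; tests check it against an
independent recursive oracle.) Cross-correlation is evaluated at zero lag
on the aligned grid — it is the "instantaneous" counterpart to DTW's
elastic matching — and is undefined (NaN) for constant series.

Distances are negated and min–max normalized **within one session of one
pair**, so `dtw_norm` ranks a trial's synchrony against that session's other
trials; with a degenerate range (all distances equal, or one trial) every
trial gets 0.5, asserting neither extreme. The model weight is
`gamma_t = gamma0 * dtw_norm`, hence bounded by `gamma0`, and `gamma0 = 0`
reproduces the reward-free model bit-for-bit (a tested invariant).

## Synthetic data

The simulator reproduces the experimental design: 12 objects, 3 per
category × difficulty cell, each in two handle orientations — 24 stimuli —
presented in a seeded order that is exactly balanced in category and
difficulty (practice sessions draw a balanced subset of 8). The bot partner
is deterministic: correct on Easy objects, always incorrect on Hard ones.
The human-like agent follows the category rule on Easy objects with a 5%
lapse rate and touches Hard objects with probability `hard_touch_prob`
(default 0.5): nothing in the design pins down pre-convergence behavior on
ambiguous items, so the default is maximal ambiguity, and the knob is a
modelling choice rather than an estimate. When both agents intend to touch,
each draws a latent reaction time (uniform 0.5–2.5 s) and the earlier touch
is recorded, ties to self — the log never contains two touches, so
`(a_s, a_p) = (1, 1)` cannot occur, matching the first-touch-only recording
of the task.

Synthetic gaze pairs mix a shared smooth latent trajectory (Gaussian noise
low-pass filtered with an 8-sample kernel, then variance-normalized) with
an independent trajectory at weight `rho`, plus optional lag, sensor
jitter, and missing samples. Session defaults set `rho = 0.7` for
human-pair and `0.2` for bot-pair sessions — the qualitative human > bot
synchrony ordering, chosen once; the magnitudes are not calibrated to any
measured effect. What the generator does **not** emulate: saccade/fixation
microstructure, object-locked gaze events, convergence of human behavior
across trials, or device-specific noise. Passing tests therefore show that
the pipeline and model behave correctly under controlled coupling and a
known design, not that the empirical effect sizes would be reproduced on
real recordings.

## Evaluation

Self-prediction accuracy is the exact-match rate between the argmin-G
action and the observed self action; partner-prediction accuracy thresholds
the predicted touch probability at ≥ 0.5 (0.5 counts as predicting a
touch). The classification suite treats a partner touch as the positive
class; precision/recall are reported as missing when undefined, F1 is 0
when both are 0, AUC uses the Mann–Whitney tie convention (ties count ½),
and MCC/AUC are missing — not zero — when only one class was observed.
Metrics pool over everything passed in; grouping is the caller's choice.
Trajectory summaries average per-trial-position accuracy and minimum free
energy across sessions, over the 12 Hard-object positions by default, since
those are the trials where category ambiguity makes convergence visible.
The post hoc power helper computes two-tailed z-test power
`Phi(|mu|/sigma - z_crit) + Phi(-|mu|/sigma - z_crit)`.

## Problem sizes and numerics

The acceptance script simulates 14 bot-pair sessions (the design's
sample size) at `gamma0 = 0.9`, recovers a fixed partner policy
(P = 0.7) from 500 trials, and contrasts mean DTW at `rho = 0.1` vs
`rho = 0.9` over 50 seeded pairs; trend statistics at 14 sessions carry
visible Monte Carlo noise, which the early-vs-late phase means (first vs
last 4 Hard positions) smooth but do not remove. All logs are natural; the
KL clip (`1e-12`) keeps boundary beliefs finite, and the softmax subtracts
the minimum free energy before exponentiating. All randomness flows through
`numpy.random.default_rng` seeds carried in the session/config objects.

## Limitations

The model is exactly the binary-action, two-conditional architecture: no
per-object beliefs, no continuous states, no fitting of `kappa`, `lambda0`,
`tau` or the EMA decay. The simulator's human agent does not itself
converge, so long-run self-prediction accuracy against it plateaus near the
ambiguity level rather than approaching 1. Cross-correlation lag search,
gaze-object sequences, fixation detection and the inferential statistics of
condition comparisons are out of scope.
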