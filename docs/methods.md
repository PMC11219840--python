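# Methods

This package reconstructs, on fully synthetic data, the analysis chain used
to study how perirhinal cortex populations reorganize while animals learn a
whisker-based delayed non-match-to-sample (DNMS) task: calcium event
estimation, a calibrated linear-decoding suite, a choice-selectivity index,
an autoencoder familiarity model, and a GLM of bulk acetylcholine signals.
Because no real recordings ship with the package, every analysis is
validated by *recovery*: the synthetic generator plants known effects, and
each analysis must find exactly those effects and nothing else.

## The task world

A trial is `pre-stimulus (1 s) | sample (1 s) | delay | test (1 s) | report
(1.5 s) | post (1 s)` at 32.6 Hz.  The sample and test stimuli are rotor
movements with a direction (anterior/posterior) and a speed (fast/slow).
Non-matching direction pairs are rewarded under go/no-go: lick on non-match
= hit, withhold = miss; lick on match = false alarm (FA), withhold = correct
rejection (CR).  Reward is delivered 0.3 s after report onset on hit trials.

Training stages follow the head-fixed schedule: T1 ramps the nonmatch
probability from 0.9 to 0.5 over five sessions; the second nonmatch
condition (PA) appears at T3; delays grow to 2 s at T4; T5 draws delays of
2/3/4 s with probabilities 0.5/0.25/0.25 and raises the slow-speed fraction
from 5% to 25%.  The sample/test/report durations and the post-trial gap are
not part of the published schedule; the values above are declared defaults
chosen to match the order of magnitude of the task's figure time axes, and
are configurable per stage.

Outcomes are drawn from a symmetric signal-detection criterion: hit rate
Phi(d'/2), false-alarm rate Phi(-d'/2), so fraction correct equals
Phi(d'/2).  This reproduces the task protocol's anchors (80% correct at d' ~
1.68, 70% at d' ~ 1.05).  Default per-stage d' values (0.6 at T1, 1.7-1.9
later) sit just above each stage's advancement criterion, i.e. the
performance a trained animal actually shows at that stage.

### Planted population codes

Neuron identity — role (direction / speed / reward / expected-outcome /
untuned), within-role preference, and a lognormal response-gain multiplier
(sd 0.5 on the log scale) — is drawn from per-neuron streams keyed by
`(effects_seed, neuron_index)`, so enlarging a population never reassigns
existing neurons; the per-session stochastic draw (spikes, photon noise)
uses a separate noise seed, so the *same* population can be re-imaged across
sessions, which is what cross-session decoding requires.  Spikes are Poisson
per frame around a 0.3 Hz baseline with additive rate bumps:

* **Direction cells** respond to their preferred direction (anterior or
  posterior, split 50/50) during sample and test, with a per-stage gain that
  decays to zero by T5 on correct trials but stays at its naive (T1) value
  on error trials.
* **Speed cells** prefer slow or fast (50/50) and respond to their preferred
  speed with a gain that grows across stages, plus an extra error-trial gain
  (`speed_error_bias`) after T1 — the substrate of the choice-selectivity
  analysis.
* **Reward/outcome cells** carry a mixed-sign outcome code, as real outcome
  populations do: ~70% are hit-responders firing from `reward_frame - lead`
  to trial end on rewarded trials, with a per-stage lead growing from 0 s
  (T1) to 2 s (T5) — the retrograde expansion; the rest are reward-omission
  responders firing from the expected reward time on unrewarded trials.
  The mixed signs matter: with a homogeneous all-positive code, a decoder
  with *permuted* weights still classifies perfectly, so weight-shuffle
  nulls saturate and nothing is ever significant.  Each hit-responder
  prefers one nonmatch condition (AP or PA) and responds to the other at a
  fraction `reward_condition_alignment` of its gain (1 = one shared
  abstract code, 0 = disjoint condition-specific codes).
* **Expected-outcome cells** carry a weak pre-stimulus rate offset toward
  their preferred future outcome (hit or non-hit, 50/50) and a strong report
  response whose preferred class is *reversed* when `expected_sign_flip` is
  set — the mechanism that drives pre-stimulus-trained decoders below chance
  at report.

Fluorescence is the AR(1) convolution of the spikes (decay 0.5 s) plus white
Gaussian noise (sd 0.3, about a third of a unit event).  The bulk ACh trace
is a pre-stimulus boxcar (amplitude 1.5) on every trial plus a component
locked to pre-reward licks (0.6 per lick, Gaussian-smoothed), Gaussian
noise, and per-trial z-scoring; deliberately, nothing is locked to reward
consumption.

What the generator does **not** emulate: correlated noise across neurons,
drifting baselines, slow representational drift within a stage, nonlinear
calcium saturation, or motor/whisking covariates.  Passing tests therefore
demonstrate that the analyses are correct and calibrated — not that they are
robust to every nuisance structure of real two-photon data.

## Calcium event estimation

Per neuron: (1) floor the trace at its bottom 10th percentile (flooring
rather than zeroing preserves the baseline level for the noise estimate);
(2) estimate the shot-noise level `v = median_t |F_{t+1} - F_t| /
sqrt(f_r)`; (3) fit an AR(1) decay coefficient from the lag-2/lag-1
autocovariance ratio, clipped to (0.5, 0.999), falling back to the 0.5 s
default (flagged) when the trace shows no usable autocorrelation; (4)
deconvolve by a pool-adjacent-violators active-set sweep solving

    min_{s >= 0}  1/2 ||F - c||^2 + lambda ||s||_1,   c_t = gamma c_{t-1} + s_t

(the AR(1)-constrained sparse problem; the unit suite verifies optimality
against an independent bound-constrained quadratic-program solver to 1e-6);
(5) normalize events by the noise level, `s_hat = s / v`.

The default penalty is `lambda = v * sqrt(T) / 2`.  A noise-scaled penalty
keeps `s_hat` invariant to per-neuron gain; the factor 1/2 was chosen
because task-locked rate structure inflates the autocovariance-ratio
estimate of gamma slightly (~0.96 fitted vs 0.94 generated on default
sessions), and the larger penalty then oversmooths single events — with the
halved default, median per-neuron Pearson correlation between `s_hat` and
the true spikes stays at 0.82-0.87 across seeds under default noise.
AR(2) kernels (explicit rise time) are a documented extension point; the
AR(1) case is the standard one and suffices for the synthetic data.

## Population decoding

Features: per neuron, `s_hat` averaged over a trial window, z-scored across
trials (zero-variance columns map to 0).  Decoders are maximum-margin linear
classifiers (squared-hinge SVM, C = 1 — the value is not documented in the
source analyses; C = 1 is the conventional default and is configurable).
The bias term is effectively unpenalized (large intercept scaling);
otherwise the solver smuggles the bias into near-constant feature columns —
e.g. condition-silent neurons — creating spurious cross-condition transfer.
Accuracy is the mean over 10 stratified CV folds; final weights are refit on
all trials.  Ties at decision value exactly 0 go to the negative class.

* **Imbalanced labels** (speed, choice): the training-split minority class
  is resampled with replacement to match the majority; the full CV is
  repeated (default 100 resamples).  Held-out performance is the *balanced*
  accuracy (mean of per-class accuracies), so chance sits at 0.5 even at a
  95/5 split — raw accuracy would saturate at the majority base rate and
  hide any learning-related change.
* **Label-shuffle null**: training labels are permuted within each fold
  before fitting; evaluation is against the true held-out labels; 1000
  repetitions give the 95th/5th percentile band.  On 200 label-independent
  sessions, ~5% of session decoders exceed the 95th percentile (verified in
  the acceptance suite), and resampled decoders at 95/5 imbalance show no
  inflation.
* **Cross-temporal decoders** train on a named period (or sliding 1000 ms
  window, step 250 ms) and test on sliding 300 ms windows stepped by 100 ms.
  Trials are aligned on a canonical axis: trial start for pre-stimulus +
  sample, each trial's own test onset for test + report (the delay segment
  uses the session minimum), so mixed T5 delays do not smear test-locked
  activity.  Steps and the alignment rule are declared defaults; the source
  states only the window widths.  Significance per window comes from a
  weight-shuffle null (permuting the weight vector across neurons, bias
  kept, no refit, 1000 repetitions): each fold model's weights are permuted
  with shared permutations and scored under the same held-out scheme as the
  actual accuracy, so the null carries the same sampling noise as the
  statistic it calibrates; per-window 95th/5th bands follow.
* **Decodable onset**: earliest significant window in the test+report span,
  with significance assessed against a max-statistic threshold — the 95th
  percentile of the *maximum* null accuracy across the span (one shared
  permutation per null draw) — which controls the familywise false-onset
  rate at 5%.  The literal per-window reading (`corrected=False`) admits a
  5% false flag per window, which across ~10+ pre-signal windows corrupts
  the "first significant window" in a sizeable fraction of sessions; a
  consecutive-window requirement (`min_consecutive`) is also available.
* **Cross-session decoders** apply a frozen model to another session of the
  same neurons (features re-z-scored within the target session), against a
  weight-shuffle null.
* **Cross-condition decoders** split nonmatch trials by condition (AP vs
  PA) into train/test, split match trials randomly, train hit vs non-hit on
  report activity, and evaluate cross-temporally on the held-out condition;
  the summary statistic is the 300 ms window ending at the end of the test
  period.  "Non-hit" pools miss, FA and CR.

The onset-recovery and below-chance ("sign-flip") properties are validated
at a scaled-down problem size — 20 seeded sessions of 80 trials x 24-30
neurons — with a >= 90%-of-seeds success criterion, the package's chosen
replicate count for stochastic end-to-end checks.

## Choice selectivity

For neurons with significant speed-decoder weights (weight outside the
5th-95th percentile of its own label-shuffled distribution), the stimulus
response SR is the peak of the trial-averaged event rate in the sample or
test period, computed separately for correct (hit, CR) and error (miss, FA)
trials; choice selectivity is `(SR_error - SR_correct) / (SR_error +
SR_correct)`.  The peak is taken on the trial-averaged trace (not per trial);
zero-denominator records are dropped and logged rather than set to 0.

Two operating characteristics worth knowing: the weight-significance
statistic has power only for reasonably sparse codes (when many redundant
neurons share a signal, each one's weight is small and sits inside its
shuffled band), and the peak statistic carries a small positive CS bias
whenever error trials are fewer than correct ones (the noisier average has
a higher peak).  The recovery tests therefore plant a sparse speed
population and compare CS across stages rather than against exact zero.

## Familiarity model

Four condition prototypes on the corners of [-1, 1]^2 (direction x speed)
are jittered with Gaussian noise (sd 0.5) and projected to 10 dimensions by
a fixed random matrix.  A single-hidden-layer autoencoder (10 noisy-ReLU
units, additive noise sd 1) reconstructs the input; an auxiliary sigmoid
logit classifies direction, breaking the symmetry between the two stimulus
variables.  The loss is `0.1 * MSE + 1 * cross-entropy + 1 * mean |hidden|`,
trained with Adam (lr 0.002, batch 10) for 50 epochs; 400 trials per
simulation.  After each epoch, an independent logistic readout (5-fold CV)
decodes direction and speed from the familiarity signal — the *signed*
difference between reconstruction and input.  Averaged over simulations,
direction decodability falls from its early peak while speed rises, and the
reconstruction-only ablation (beta_r = 1, others 0, lr 0.01) shows no
comparable split.

Choices the source description leaves open, fixed here after verifying the
dissociation holds at the defaults: hidden width 10 (= input width);
sparsity normalized as the mean of |hidden| over batch *and* units (the
per-sample L1-sum variant at beta_s = 1 drives the hidden layer entirely
dead); uniform fan-in initialization (the standard Linear-layer default);
projection entries of sd 1/N_inp, which places the projected signal at the
scale of the hidden-noise floor at initialization — this is what makes early
familiarity noisy enough for speed decodability to *rise* with training
rather than start at ceiling.  Hidden noise is applied at both training and
readout time.  The network and Adam are implemented directly in numpy with
analytic gradients (verified against finite differences); the model is small
enough that an autodiff framework would add nothing.

## Acetylcholine GLM

The per-session design matrix has boxcars for the pre-stimulus period, each
stimulus direction (that direction's sample + test frames), the 300 ms
post-reward window, and the post-trial period, plus lick trains convolved
with a 10-sample Gaussian kernel (sd 2 samples, unit mass — the width is not
documented; 2 samples keeps the kernel inside its 10-sample support) and
split into pre-reward licking (all licks on miss/FA/CR trials; pre-reward
licks on hits) and post-reward licking (hit trials only).

Fits are identity-link Gaussian with an L1 path of 6 penalties, log-spaced
over three decades down from the smallest all-zero penalty, selected by
4-fold CV deviance and refit on all frames.  Deviance is the residual sum of
squares at unit dispersion (a fixed Gaussian constant, so AIC differences
between nested fits are well defined); `AIC = 2k + deviance` with k the
count of nonzero parameters including the intercept (an all-parameters mode
is available).  Factor importance is `dAIC = AIC_partial - AIC_full`, the
partial model refit with the same penalty path after removing the factor's
covariates; the two direction covariates form one factor.  On the synthetic
trace the pre-stimulus factor dominates and reward/post-reward-licking
factors hover at or below zero, matching the generator's construction.

## Behavior rules

`d' = Phi^-1(HR) - Phi^-1(FAR)` with rates clamped to [1/2N, 1 - 1/2N].
Stage advancement: d' > 0.45 for two consecutive sessions at T1, > 1.68
thereafter.  Adaptive rules on sliding windows (50 trials for punishment, 20
for biases): < 70% correct adds 1 s time-out (max 10 s) and, beyond a 7 s
time-out, one air puff (max 5); > 50% misses removes 2 s and 2 puffs
(floored); report bias X - Y > 0.25 / > 0.5 moves the stimulus split to
0.35/0.65 / 0.2/0.8 toward the neglected port.  The training protocol's primacy/recency
criterion "(X/Y - 0.5) > 0.55 (moderate), > 0.6 (severe)" is implemented
literally as ratio-minus-half (default) — note that taken literally it fires for
almost any X > 1.05 Y — with a difference-based mode (`X - Y`, same
cut-offs) available, since the literal expression is plausibly a transcription error in the protocol.

## Problem sizes and determinism

Default validation sizes — 150-200 trials and 24-60 neurons per session,
100-500 null repetitions, 20 simulations for stochastic properties — were
chosen so the full suite exercises every pathway at desk scale; every
generator and analysis accepts a seed or `numpy.random.Generator` and is
bit-reproducible under a fixed seed.  Null-band percentiles use numpy's
linear-interpolation percentile.  Known limitations: the decoding suite
assumes binary labels throughout; nonlinear decoders, ROC-based selectivity
and real-data loaders (e.g. NWB) are out of scope.
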