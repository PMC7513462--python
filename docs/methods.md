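# Methods

This note documents the generative model behind the synthetic MEG data, the
conventions of each analysis stage, the designs of the validation studies,
and the choices made where the design was genuinely open.

## The simulated experiment

### Trial design

A simulated session presents morphed characters whose single morphable
"pixel" takes one of eight equally spaced contrasts on [0, 1]; steps 1 and 8
are unambiguous endpoints (one letter, one digit per continuum).  Five trial
features are manipulated:

| feature | code | definition |
|---|---|---|
| position | ±1 | stimulus left/right of fixation |
| identity | ±1 | which morph continuum (e.g. E–6 vs H–4) |
| category | ±1 | letter vs digit; on ambiguous trials defined by the *report* |
| uncertainty | [0, 1] | 1 − \|2c − 1\| for pixel contrast c (0 at endpoints, max 6/7 on an 8-step grid) |
| motor | ±1 | button pressed = mapping × identity × reported category |

Active trials form a full factorial over {position(2) × continuum(2) ×
step(8) × mapping(2)}, replicated and shuffled; the identity→button mapping
alternates across blocks, so every block carries a single mapping level.
Because the motor code is the three-way product of mapping, identity and
(reported) category, all five features are pairwise uncorrelated over a full
factorial — exactly zero at design time, and approximately zero after
behavior is simulated (reports redefine the category code on ambiguous
trials).  Passive trials (default 8 per block, appended at block end) use
unambiguous endpoints of two held-out continua, and carry neither motor code
nor reaction time.

The default desk-scale design is 12 blocks × 40 trials (384 active + 96
passive); the full-scale layout (40 blocks, 1920 trials, 320 passive) is one
configuration away.

### Behavior

The probability of reporting "letter" is logistic in letter evidence,
`P = σ(k·(e − ½))` with slope k = 8 by default, which yields endpoint
accuracy near ceiling and ambiguous-step accuracy near 60–70%.  Reaction
time is a base (450 ms) plus one positive delay per processing stage.  Each
delay is `scale · (1 + w·u) · lognormal(σ)`: proportional to a per-stage
scale (0/40/60/50/50 ms), increasing with trial uncertainty u (weight w,
default 1), and log-normally dispersed (σ = 0.3 by default).  Setting all
stage scales to zero makes RT exactly the base on every trial; setting
w = 0 makes RT dispersion independent of the stimulus (used by the
latency-gain recovery study, below).

### Epochs

Epochs default to −300…+1500 ms at 250 Hz (the validation studies use
−100…+900 ms at 50–100 Hz to stay fast); channels are generic sensors, or
sources on a unit sphere (Fibonacci lattice) whose y axis is
postero-anterior.  Each feature contributes, per trial i,

    amplitude · v_i · env(t − Δ_i) · pattern(t − Δ_i)

with independent white Gaussian sensor noise (sd 1) on top.  The pieces:

- **Readout v_i.**  For binary features the signed evidence (±1, scaled by
  |2·evidence − 1| for category/motor so ambiguous trials carry weaker
  codes); `readout="linear"` leaves it graded, `readout="sigmoid"` saturates
  it through tanh(g·s)/tanh(g) (g = 6), approximating an all-or-none code.
  The graded uncertainty feature uses its normalized code on [−1, 1].
- **Envelope.**  Half-Hann rise from onset to peak.  The fall is a mixture
  (default ½/½) of a fast half-Hann mirroring the rise and a slow half-Hann
  reaching zero at the offset.  A single Hann fall spanning a
  many-hundred-ms decodability window makes the score curve almost flat
  after the peak, so the planted peak latency is barely identified; the
  two-timescale fall gives the peak a well-defined curvature while keeping
  decodability alive until the offset — the transient-plus-sustained
  structure typical of evoked components.
- **Pattern dynamics.**  The unit-norm channel pattern rotates within a
  random 2-D channel subspace; a full rotation takes
  `rotation_period_ms / (1 − stability)` ms (default period 250 ms at
  stability 0; stability 1 is static).  This is the generative mechanism for
  diagonal temporal generalization, with the rotation timescale calibrated
  so row durations fall in the few-hundred-ms range typical of
  sensor-level reading paradigms rather than being near-static across the
  epoch.  In source space the pattern is spatially weighted by a Gaussian
  along the postero-anterior axis centered at `pattern_center_y`.
- **RT coupling.**  A per-trial shift Δ_i = rt_coupling · (rt_i − mean rt)
  delays the *whole trajectory* — envelope and pattern phase together.  A
  slowed neural process delays everything it does; shifting only the
  envelope would leave the pattern trajectory locked to absolute time and
  make the shift almost invisible to generalization-based latency analyses.
- **Passive trials** never carry a motor code; `active_only` components are
  silenced on them; non-`abstract` components use a passive-set pattern
  orthogonalized against the active one, so an abstract-code decoder cannot
  transfer to it even in a low-dimensional channel space.

Default feature parameters plant the cascade at peaks 120 / 225 / 370 / 590 /
604 ms (position / identity / category / uncertainty / motor), with onsets
and offsets spanning the corresponding decodability windows, stabilities
0.75–0.85, and amplitudes (1.6 / 0.7 / 0.6 / 0.8 / 1.2 in noise-sd units)
calibrated so default decoding spans the strong-to-weak range typical of
sensor-level MEG (position near ceiling, category weak).  Cohorts add
per-subject variation: each feature's whole time course is shifted by
N(0, 6 ms) and its channel pattern re-seeded per subject.

Continuous disk reports (for the psychophysics-only experiment) are a
logistic — or, as a control, linear — function of evidence plus Gaussian
noise; a 15% lapse fraction gets near-zero visibility and a random angle,
and trials below a 5% visibility floor are flagged for exclusion.

## Analysis conventions

- **Decoding.**  One l2-regularized model per time sample (temporal) or per
  channel (spatial): logistic regression (C = 1) for binary targets,
  ridge (α = 1) for graded ones — deliberately no hyperparameter search.
  Stratified (classification) or plain (regression) 5-fold CV with a fixed
  seed; channels standardized by the training fold's mean/sd only
  (numerically dead channels — sd ≤ 1e−12 relative — are neutralized with a
  warning).  Scores: rank-based AUC with mid-rank tie handling (equal to the
  pairwise count P(s⁺ > s⁻) + ½P(tie)), or Spearman r.  A leakage guard is
  enforced by test: corrupting held-out trials changes no fitted weight or
  scaler statistic, bit for bit.
- **Temporal generalization.**  The pipeline trained at t (model + scaler)
  is applied wholesale at every t′ within the fold; the TG diagonal
  reproduces temporal decoding exactly (same folds, same arithmetic).  The
  *row duration* at train time t is the contiguous significant run of test
  times containing the diagonal sample (both directions — under this
  definition a full-square mask gives mean row duration equal to the
  diagonal duration, and a band of width w gives w); the *diagonal duration*
  is the significant extent of the diagonal.  Their ratio is the
  square-vs-diagonal summary: 1 for stable codes, small for dynamic ones.
- **Cluster statistics.**  One-sample t against chance per element,
  one-sided cluster-forming threshold at p < 0.05 by default (decoding
  scores only meaningfully exceed chance), connected components under a
  time-chain, train×test-grid, or spatial-graph × time-chain adjacency,
  summed-t cluster mass, and a max-statistic null from random whole-subject
  sign flips.  p = (1 + #{null ≥ obs})/(1 + n_perm); when 2^n_subjects ≤
  n_perm all sign patterns are enumerated and p is exact.
- **Psychometrics.**  The sigmoid is `y = β₀ + 1/(1+exp(−β₁(x−β₂)))` with
  β₁ > 0 (monotone increasing; this fixes the sign ambiguity of the
  exponential's argument).  Initialization: β₁ from the central finite
  difference (×4), β₂ at the central evidence value, β₀ = min(y).  Because
  the two models differ in parameter count they are compared on held-out
  points only; on level-averaged curves (8 points per morph) the held-out
  predictions are pooled across folds before correlating ("pooled"
  scoring), since per-fold Pearson r is undefined on 1–2 points.
- **Encoding.**  OLS with z-scored feature columns (betas comparable across
  features) plus an intercept; per-trial pre-stimulus baseline subtraction;
  rank-deficient designs raise an error naming the most collinear columns.
- **RT-binned latency analysis.**  Decoders are trained on all trials
  (within CV); held-out decision values are pooled across folds, split into
  RT quantile bins, scored per (bin, train time, test time), and averaged
  along diagonals into per-bin lag curves.  Only lags for which *every*
  train time has a valid test sample enter the average — partial coverage
  creates an unshifted edge artifact shared across bins that swamps small
  latency shifts.  Three latency estimators are provided: smoothed argmax
  with parabolic refinement (the per-bin "peak latency"), the upper-half
  centroid (lower variance, but attenuates toward zero at low SNR because
  noise spreads the supra-threshold set), and leave-one-out template
  matching (cross-correlation of each bin's curve against the mean of the
  *other* bins, rescaled by (B−1)/B).  The leave-one-out template avoids the
  zero-shift bias a bin's own noise induces when it is part of its own
  template; all smoothing uses edge-padded moving averages, because zero
  padding dents both curve ends identically across bins and biases any
  cross-curve alignment toward zero lag.  Per-feature gains are the
  regression slopes of per-bin shifts on bin mean RT, tested against zero
  across subjects with a signed-rank test.
- **Readout shape.**  Held-out classifier probabilities (logistic link, not
  hard labels) from window-averaged data, related to graded evidence at the
  trial level with the psychometric CV comparison; the interaction is the
  late-minus-early difference of (r_sigmoid − r_linear) per subject.
  Default windows 200–400 and 500–700 ms.
- **Architecture simulations.**  Units are (layer, feature, phase) slots;
  layer l *generates* feature l through the generation chain
  (l, l) → (l+1, l+1), which is the part of the shift matrix F present in
  every architecture.  `broadcast` adds full forward propagation of every
  represented feature plus skip connections into the last layer; `maintain`
  adds a binary diagonal R on each layer's own-feature unit; `dynamic`
  replaces stable maintenance with a two-unit 90°-per-step rotation (the
  minimal mechanism that preserves information in changing activity);
  `hybrid` combines propagation with rotational maintenance.  Weights
  default to 1 with a spectral-radius warning above 1.  The delay
  experiment freezes a stage — its units hold their state, nothing reads
  from them — for a configurable number of steps, which shifts every
  downstream ignition by exactly the delay and leaves upstream layers
  untouched; multiple stage delays compose additively downstream.
  Predicted decodability uses a threshold of 1e−6 of the peak activation.

## Validation studies

All studies run from a single master seed through independent substreams.

1. **Cascade recovery** — 17 subjects at the default spec (20 channels,
   100 Hz, 384 active trials); group peak = parabolic argmax of the
   5-sample-smoothed subject-mean curve, onset = first significant cluster
   start.  Expected: planted order recovered, each peak within ±40 ms.  The
   group-mean curve (rather than averaging per-subject argmaxes) is the
   standard way to report group latencies and is what makes the 14-ms
   uncertainty/motor separation resolvable at all.
2. **TG signatures** — 20 replicates of 60-trial ensembles of the maintain
   and dynamic hierarchies (unit-activation noise sd 0.5); TG thresholded
   at 0.8 (decoders trained at no-signal times can reach fold-averaged
   AUCs near 0.85 at signal times through sign-random weights, while
   diagonal cells cannot, so 0.8 cleanly separates) and summarized by the
   row/diagonal ratio.
3. **Dynamical-system oracle** — 100 random small systems against the
   matrix-power convolution closed form at 1e−12, plus exact delay-shift
   checks on a skip-free feedforward chain.
4. **Cluster calibration** — 200 pure-noise cohorts (8 subjects × 50
   samples, 512 flips); the family-wise false-positive rate should sit in
   the exact binomial 95% CI around 0.05.  The exhaustive path is checked
   against an independent enumeration oracle.
5. **Psychometric discrimination** — 100 cohorts of 8 subjects × 4 morphs ×
   8 levels × 12 reports (report noise 0.35, 15% lapses, low-visibility
   exclusion); sigmoid-generated cohorts should prefer the sigmoid model
   (one-sided signed-rank p < 0.05) in ≥95% of cohorts, linear-generated
   cohorts near-never.
6. **AUC / OLS oracles** — exact agreement with O(n²) pairwise counting on
   1000 tie-rich instances; encoding betas against the pseudo-inverse at
   1e−8.
7. **Latency-gain recovery** — gains (0, 0, 0.5, 0.5, 1.0) along the
   hierarchy, 100 single-subject replicates (16 channels, 50 Hz, 192 active
   trials), behavior with w = 0 and RT noise σ = 0.6: the gain study needs
   RT variance that is independent of stimulus ambiguity, otherwise RT
   quantile bins become single-class for the binarized uncertainty target.
   Gains are recovered by template matching within per-feature train
   windows capped at 660 ms (so ±240 ms of lag has full coverage).  The
   estimator shows a small (≲10%) attenuation from within-bin shift
   dispersion and lag-window truncation.
8. **Readout interaction** — category planted as an early linear
   (150–450 ms) plus late saturated (450–750 ms) component; 20 replicates
   of 17-subject cohorts; the trend × window interaction should be
   positive essentially always.  Note the logistic link itself bends
   linear codes toward a shallow sigmoid, so the early window's "linear"
   advantage is only required to be non-negative-ish; the interaction is
   carried by the late window.
9. **Leakage guard** — bitwise identity of all fitted weights, intercepts
   and scaler statistics under arbitrary corruption of held-out trials.

## What the generator does not emulate

Sensor noise is white and independent across channels and time — no 1/f
spectrum, no channel covariance (an optional correlation structure would be
a straightforward extension), no physiological artifacts, no bad channels,
no head movement, and no forward-model leakage between sources (source
"patterns" are spatially weighted draws, not lead fields).  Trials are
exchangeable: there is no learning, fatigue or serial dependence, and the
feedback events of the task are represented in the design but generate no
neural code.  Passing the validation suite therefore demonstrates that the
*analysis machinery* is correct and calibrated under its own assumptions —
it does not certify performance on real recordings, where correlated noise
and leakage can widen cluster nulls and blur spatial attributions.

## Numerical notes and degenerate inputs

- Decoding standardization treats sd ≤ 1e−12·max(1, |mean|) as zero
  variance (warns, neutralizes the channel).
- AUC requires both classes; single-class folds raise; single-class RT bins
  yield missing scores rather than errors.
- Sigmoid fits flag constant responses as degenerate and report
  non-convergence with diagnostics; Wilcoxon tests return p = 1 (flagged)
  for all-zero differences and refuse n < 5.
- Cluster tests refuse n < 2 subjects, warn below 5 subjects or 100
  permutations; empty supra-threshold sets return an empty result, not an
  error.
- Peak interpolation falls back to the grid argmax at curve boundaries;
  peak normalization refuses curves that never exceed chance.
- All seeds derived from master seeds stay below 2³¹.

## Known limitations

- The latency-gain estimator's small attenuation (item 7 above) is
  inherent to quantile binning with dispersed within-bin shifts; a
  single-trial latency model would remove it at the cost of much higher
  variance.
- Generalization durations count the contiguous run through the diagonal;
  codes that resurface non-contiguously (e.g. periodic rotation revivals)
  contribute only their first run.
- The archsim "dynamic" mechanism is one concrete minimal choice
  (two-unit rotation); other dynamics that produce diagonal TG exist and
  are not distinguished.
- Spatial decoding attributes a feature to the channel whose time course
  best decodes it; with correlated noise or mixed patterns this attribution
  is optimistic compared to real source-space analyses.
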