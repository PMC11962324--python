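# Methods

`moodcast` forecasts next-day emotional valence and binarized PHQ-9 item
responses from passively sensed daily behavior, and scores day-level risk of
an emotional-state change. The pipeline has three separately trained stages —
a heterogeneous hidden Markov model (HMM) that embeds incomplete mixed-type
daily features as hidden-state posteriors, an encoder–decoder transformer
that forecasts the posterior sequence, and windowed classification heads —
plus information-theoretic change scoring on the predicted valence
distributions. All stages are exercised against a synthetic cohort generator
with known ground truth.

## Data model

One row per patient-day with seven behavioral features: step count, covered
distance (km), sleep (h), app use (h), time at home (h), visited-places
count (all continuous), and a binary practiced-sport indicator. Any subset
may be missing. Self-reported valence (negative/neutral/positive = 0/1/2)
and PHQ-9 item responses are sparse targets. Sequences are calendar-daily;
gaps are filled with all-missing rows (`preprocessing.regularize_days`), and
days are indexed 0-based from each patient's first observation.

## Preprocessing

Quality control replaces negative sensor totals with missing (a negative
total is an artifact, not evidence of zero activity), clips values above
their physical caps (24 h for time-denominated features, 30,000 steps/day,
500 km/day), and coerces the sport flag to {0, 1, missing}. QC is idempotent
and never imputes. Continuous features are standardized to mean 0, SD 1
with parameters fitted once on the HMM training subset and frozen; fitting
on a single subset (rather than all patients) avoids leaking held-out
patients' statistics into later stages. Daily valence is the sign of
(positive − negative) emotion-report counts, ties mapping to neutral.
PHQ-9 items (0–3) are binarized at ≥2 ("more than half the days" or worse).
Patients are partitioned 30/40/30 (HMM / transformer / classifiers) by
stratified largest-remainder sampling within each clinical cohort, so no
patient contributes to more than one training stage.

## Heterogeneous HMM with exact missing-data marginalization

Hidden states follow a first-order chain λ = (π, A, B); emissions are
conditionally independent given the state: diagonal Gaussians for the six
continuous features and a Bernoulli for sport. Because emissions factorize,
a missing feature is marginalized exactly by omitting its term from the
emission log-likelihood; a fully missing day contributes nothing and its
posterior follows the chain alone. Inference uses scaled forward–backward
recursions (per-day emission rows are max-shifted before exponentiation, so
no underflow occurs for any sequence length). Fitting is Baum–Welch with an
observed-weighted M-step: every sufficient statistic is weighted by
γ · observation-mask, so parameters are estimated from observed values only.

Numerical choices: SD floor 1e-3 (standardized units) prevents variance
collapse; Bernoulli rates are clamped to [1e-6, 1−1e-6]; transition rows are
floored at 1e-12 and renormalized. Initialization is k-means on
complete-case days (falling back to mean-filled rows when complete cases are
scarce), a uniform transition matrix with a 0.8 self-transition boost
(behavioral regimes persist day to day), and uniform π; the default is 5
restarts keeping the best final likelihood, all seeded. States whose
expected occupancy falls below 0.1% of the per-state average are re-seeded
from a random observed day with a warning.

Model selection: AIC = 2p − 2ℓ and BIC = p ln n − 2ℓ with
p = (K−1) + K(K−1) + 2·F·K + K (start, transitions, Gaussian mean+SD per
continuous feature, Bernoulli per state) and n = the number of *observed*
feature values. The package default is K = 7 states, overridable;
`select_K` reproduces the information-criterion sweep on a subset of
sequences.

The T×K matrix γ of smoothed state posteriors is the daily embedding passed
downstream. Note that smoothing uses the whole observed sequence; when
posterior sequences are later windowed for classification, day-t features
may therefore carry weak backward-smoothed evidence from later observations.
This mirrors the standard practice of computing posteriors per recording and
is called out here because it slightly flatters day-level alignment in
change detection.

## Transformer forecaster

An encoder–decoder transformer is trained self-supervised to forecast the
posterior sequence one day ahead. Architecture: input projection K → 32
plus fixed sinusoidal positional encoding; 3 encoder layers (multi-head
self-attention, position-wise feed-forward, residual + layer-norm around
each sublayer); 3 decoder layers adding causally masked self-attention and
cross-attention over the encoder output; linear output head K logits.
Defaults: embedding 32, 4 heads, feed-forward 128, dropout 0.3, Adam at
lr 1e-3, MSE loss (MAE available), 80 epochs with early stopping
(patience 10) on a 10% window-level validation split, restoring the best
weights. Windows span 30 encoder + 20 decoder days, stride 1, with the
training target the decoder segment shifted one day ahead (teacher
forcing). Everything is implemented on an in-repo numpy reverse-mode
autodiff engine (`moodcast.nn`) whose gradients are verified against finite
differences; training is bit-deterministic given the seed.

Two departures from the vanilla architecture, both motivated by
autoregressive stability on persistent regime data:

* **Persistence skip.** The decoder output adds 0.5·log(clip(input, 0.01))
  to the logits, so the untrained model already leans toward persistence
  (softmax of tempered log-probabilities) and training learns the departure
  from it. The temper and clip floor keep the initial softmax away from
  saturation, where MSE gradients vanish.
* **Decoder input noise.** During training each decoder-input day is mixed
  toward the uniform simplex with a weight drawn uniformly from [0, 0.5].
  At inference the decoder re-feeds its own softmax outputs, which are
  softer than true posteriors; without this augmentation the learned
  one-step map is only accurate on sharp inputs and iterating it drifts to
  a spurious attractor within 3–4 steps (forecasts collapse to one state).
  With it, multi-day rollouts track the transition structure.

Raw decoder outputs are projected to the probability simplex by softmax;
the loss is computed on the projected outputs, keeping training and the
projection contract consistent. Autoregressive inference seeds the decoder
with the final observed day and appends each projected prediction
(prefix-consistent: the first step of an N-step forecast equals the 1-step
forecast). Horizon 0 in evaluation curves is same-day reconstruction: the
one-step prediction of day t from data through t−1.

`one_step_predictions` exposes the teacher-forced decoder outputs along a
sequence: row j is the forecast made *at* day j (from data through day j)
for day j+1. These rows are the per-day features consumed by the
classification heads; a window ending before target day t therefore uses
data through day t−1 only.

## Classification heads

Next-day valence is predicted from the flattened window of the 7 days of
decoder outputs strictly before the target day (7×K features). The default
model is XGBoost (300 trees, depth 4, learning rate 0.1, single-thread for
determinism) with class-balanced sample weights, since valence labels are
imbalanced and the headline metrics are macro-averaged; random-forest and
MLP heads are available. Tree-ensemble probability outputs are used
directly as valence distributions (no post-hoc calibration). PHQ-9 items
are nine independent binary classifiers over three feature sources —
decoder outputs ("embeddings"), decoder outputs + predicted valence
distributions, or valence distributions alone — with window lengths 3, 7,
or 15 days. Patient-level train/test separation is enforced throughout;
questions with fewer than 10 labeled instances are skipped.

## Change detection

For a daily series of predicted valence distributions, two scores over a
3-day window (the window covers the 3 days strictly before each day):
entropy (base 2) of the window-mean distribution, and the divergence
between the present-day distribution P and the window mean Q. The default
divergence is the standard Jensen–Shannon divergence
½KL(P‖M) + ½KL(Q‖M), M = (P+Q)/2 — symmetric and bounded in [0, 1] bits. A
"jeffreys" variant implements the symmetrized KL ½[KL(P‖Q) + KL(Q‖P)] with
1e-10 smoothing, preserved because the two are easily conflated in print.
Days without a full window receive no score rather than a shrunken window,
keeping scores comparable. Ground-truth change labels mark any day whose
valence differs from the most recent preceding valence. Detection is
evaluated by threshold-sweep ROC with trapezoidal AUC, optionally per
patient group.

## Synthetic cohort generator

The generator emulates the study conditions: a latent K-state regime chain
(default K = 3) drives six Gaussian features (clipped at zero — sensors
cannot report negative totals) and a Bernoulli sport flag; each feature is
masked missing independently per day (MCAR) at the per-feature rates
reported for the real cohort (52.6–69.5% for the continuous features; the
binary flag, unreported, uses the overall mean 60.2%). An optional
state-dependent missingness multiplier is available. Sequence lengths are
truncated-normal with mean 224, SD 200, minimum 50 days. Valence is
reported on 3.66% of days; PHQ-9 responses arrive with geometric gaps of
mean 25.27 days, items Bernoulli given the regime with item 9 (suicidal
ideation) most strongly coupled. The default transition matrix is
A = 0.9·I + 0.1·1πᵀ with π chosen so the stationary day-level valence
marginal under the 0.8-diagonal state→valence coupling is exactly the
reported 45.8/23.7/30.4 negative/neutral/positive split.

Valence is redrawn from the coupling row of the current state at every
regime change and, within a stable regime, with a daily renewal probability
of 0.15. Self-reported mood is strongly autocorrelated, so most valence
changes are regime-driven (hence in principle detectable from behavior)
while some within-regime fluctuation remains. A renewal rate of 1
recovers day-iid conditional sampling; note that under day-iid sampling
~18% of days would flip valence independently of behavior, which caps any
behavior-based change detector near chance and does not describe how mood
is reported in practice.

Default emission profiles overlap (~1–1.5 SD separation per feature):
behavioral regimes in real data are identifiable from the joint profile,
not from any single feature. Two optional mechanisms add longer-range
temporal structure: a weekly rhythm (weekend transition rows mixed toward a
preferred regime) and phase-type regime dwell times (`dwell_phases` r > 1
draws each dwell as a sum of r geometrics with unchanged mean, giving
regimes a typical duration) with an explicit regime-to-regime jump matrix.

Everything is reproducible bit-for-bit from the spec seed (per-patient
generators spawned from one seed sequence), and cohorts serialize to tidy
`daily.csv` / `phq9.csv` / `truth.csv`.

## Benchmark designs

Two purpose-built cohorts support the package's evaluation experiments;
their parameters are part of the experimental design, chosen for what each
experiment must be able to distinguish.

**Forecasting comparison** (`forecasting_benchmark_spec`): regimes
self-persist at 0.9/day but with phase-type dwell (r = 3, typical duration
≈ 10 days) and a preferentially cyclic regime order (withdrawn →
intermediate → active → …), mimicking deterioration/recovery cycles. Under
a purely first-order chain, both the transformer and the transition-power
baseline γₜAʰ reduce to persistence forecasting and the comparison is
uninformative (we measured a dead tie); regime cycles with typical
durations are exactly the longer-range structure an attention model can
exploit — it can read the regime age and order from its 30-day context —
while one-step extrapolation cannot. State-match accuracy (fraction of days
where the argmax of the forecast distribution equals the argmax of the true
posterior) is reported per horizon 0–7; the desk-scale experiment uses 50
patients × ~100 days, 10 training epochs, 3 seeds.

**Planted-signal benchmark** (`planted_signal_spec`): three balanced,
strongly persistent (0.95 self-transition) regimes with widely separated
behavioral profiles (~3 SDs per feature), 0.9-diagonal state→valence
coupling, valence renewal 0.05 (almost entirely regime-driven), 50% valence
reporting, and the study's default missingness. This stresses the full
pipeline — can a strong, known signal survive QC, marginalization,
embedding, forecasting, windowing, and classification? — rather than the
realism of any one stage. Desk scale: 150 patients × ~130 days, K = 3, 20
transformer epochs, 40% of classifier-subset patients held out. Thresholds
asserted on it (valence macro-F1, divergence AUC) are properties of this
synthetic design, not claims about any clinical cohort.

## What passing tests do and do not show

The generator is Gaussian-given-state with MCAR missingness and
conditionally independent features — exactly the HMM's assumptions — so
parameter-recovery results certify the estimator, not the model's fit to
real behavior. Real passive-sensing data have heavier tails, informative
(device-driven) missingness, cross-feature dependence, and non-stationary
label semantics; pipeline metrics on synthetic cohorts therefore bound what
the machinery can do when its assumptions hold, and say nothing
quantitative about clinical data. The smoothing leak noted above also means
day-level change-detection alignment is easier here than in a strictly
online deployment.

## Problem sizes and determinism

Desk-scale experiment sizes (above) were chosen so the full test suite and
the acceptance script each run on a single CPU in minutes while keeping
every assertion's sampling error well below its margin. All randomness fans
out from one root seed via `numpy.random.SeedSequence`; EM restarts,
weight initialization, dropout masks, batch shuffling, patient splits, and
tree ensembles (single-threaded) are all derived from it, and re-running
any pipeline configuration reproduces every CSV byte-identically.

## Known limitations

* The HMM supports diagonal covariance only; correlated residuals within a
  state are absorbed into extra states.
* The forecaster is trained on smoothed posteriors; a strictly online
  variant (filtered posteriors) would forecast from weaker inputs.
* Tree-ensemble probabilities are used uncalibrated; entropy/divergence
  scores inherit any miscalibration.
* The "retrained/fine-tuned" classifier variants are exposed only as
  re-training the head on a different feature source; end-to-end joint
  fine-tuning is out of scope.
* PHQ-9 items are modeled independently; the total score and the 4-level
  responses are not predicted.
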