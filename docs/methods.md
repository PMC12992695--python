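# Methods

This note documents the models and procedures implemented in `locostate`,
the assumptions behind them, the tunable parameters and their defaults,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices made where the design was genuinely open.

## Feature extraction

**Kinematics.** Features are computed per capture frame with a two-frame
sliding window advanced one frame at a time, so the feature rate equals
the frame rate (200 Hz rodent, 100 Hz human; frame period 5 ms rodent).
Derivatives use forward first differences scaled by the frame rate, with
the leading sample(s) back-filled so every feature series keeps the frame
count. Units: positions mm, speed mm/s, acceleration mm/s², angles
degrees. Joint angles are the arccos of the normalized dot product of the
two limb vectors meeting at the middle marker, constrained to [0°, 180°];
a zero-length limb vector raises an error naming the frame. Forward
movement is the per-frame x-displacement of the reference marker (the
toe/metatarsophalangeal joint) multiplied by the run's travel direction
(sign of net x displacement), so runs walked in either runway direction
produce comparable, positive-forward features. Gaps of at most 10 frames
are linearly interpolated; markers with longer gaps, edge gaps, or less
than 70% valid samples are rejected for that run.

**Neural.** Features are computed per channel on trailing (causal)
estimation windows of `est_window` seconds (default 1.0 s — matching the
embedding's 1-s receptive field) ending at each output sample, hopped at
the feature rate; output samples whose full window precedes the recording
start are back-filled with the first valid value. The panel per channel:
Hjorth activity (µV²), mobility and complexity (dimensionless, first
differences); log mean Hann-periodogram power in each configured band
(HB–LG 20–42 Hz and gamma 60–90 Hz for the rodent; beta 13–20 Hz and
gamma for the human STN), with a floor of 1e-20 guarding log(0); and
optionally burst rate and mean burst duration, defined as supra-threshold
excursions of the Hilbert envelope of the 4th-order Butterworth
band-passed signal, thresholded at the run-level 75th percentile. Raw
acquisition rates (e.g. 24,414.1 Hz) are polyphase-resampled to 1,000 Hz
before extraction — every band of interest lies below 100 Hz. The rodent
gamma band is not standardized; 60–90 Hz is the configurable default.
Feature names carry the channel and hemisphere, e.g.
`Hjorth complexity M1L (L)`.

**State-specific PSDs** use Welch's method (0.5-s Hann segments, 50%
overlap) on the first 1.5 s of each state occurrence, restricted to
5–100 Hz and averaged within state; shorter occurrences are excluded and
counted. The 20–42 Hz band mean is reported per state.

## Dataset assembly and validation design

Runs are concatenated into one multimodal matrix (kinematic block |
neural block) with per-sample state labels (half-open [start, end)
intervals; samples outside any interval are `unlabeled` — excluded from
model fitting but retained in occupancy accounting). Cleaning is
per-feature: samples beyond 4 robust z-units (median/1.4826·MAD) are set
to the feature median, then the column is Z-scored. The detection
threshold is a package choice (the replacement rule is standard, the
detection rule is not); it is configurable and recorded, together with
the medians, means and SDs, in a normalization record so held-out
partitions are always transformed with training-partition statistics.
Features left constant after cleaning are dropped and recorded.

Cross-validation is run-grouped: runs are shuffled with the split seed
and partitioned into k near-equal folds, so no run contributes samples to
both train and test of a fold. The study-scale configuration is 11 folds
over 55 runs (train 50 / test 5 per fold).

## Linear model

The LDA classifier is fitted on the full three-state vocabulary;
following the practice of grouping behaviorally confounded states in the
*report*, the evaluation optionally merges classes (akinesia + stationary
vs gait for the kinematic model; gait + stationary vs akinesia for the
neural model) on the *predictions*, leaving the classifier itself
multiclass. Analytic covariance shrinkage is engaged automatically when
the pooled covariance condition number exceeds 1e8 (or the eigensolver
fails), and is recorded on the results object. Positive-class precision,
recall and f1 are reported for the pathological/minority class (gait for
the kinematic model, akinesia for the neural model), with macro f1
alongside, because the convention (positive-class vs macro) is ambiguous
in this kind of reporting; both are computed and labeled. Permutation
feature importance is the mean drop in balanced accuracy over 10
independent permutations of one test-partition column, aggregated across
folds.

## Contrastive embedding

The encoder is a temporal convolutional network mapping the trailing
`receptive_field` samples (default 200 = 1 s at 200 Hz) of the z-scored
feature matrix to the unit sphere in `output_dim` dimensions (default 3).
The 1-s default uses a fixed 6-layer plan of valid convolutions with GELU
activations, (kernel, stride) = (8,8)(3,1)(3,2)(3,2)(3,1)(3,1), hidden
width 32 (the exact widths/strides of such encoders are implementation
details; these are the package's, chosen to consume exactly 200 samples
in 6 layers). Other receptive fields use an automatic plan builder whose
depth may differ. The network and its gradients are implemented directly
in NumPy (float32, Adam, exact backprop through the im2col convolutions
and the output normalization).

Training minimizes InfoNCE with cosine similarity at temperature 0.1:
anchors are drawn uniformly from labeled window positions; each anchor's
positive is drawn from same-label positions within ±`time_offset`
samples (default 200) in the same run, falling back to any same-label
position when the neighborhood is empty; negatives are the other
positives in the batch. Windows never straddle run boundaries; the first
`receptive_field − 1` samples of each run are excluded. Two profiles are
provided: `paper` (batch 512, 50,000 iterations — the full-scale setting,
impractical without the original data volumes) and the default `desk`
(batch 128, 2,000 iterations, learning rate 5e-4), which all tests and
examples use. The loss trace is recorded; training aborts on a non-finite
loss.

Decoding is a cosine-metric 3-nearest-neighbor vote on embedded windows,
with ties broken by the nearest neighbor. Embedding-space feature
importance permutes one feature column of the *test block before
embedding* and reports the drop in decoder macro f1. A shuffled-label
control (labels permuted over labeled samples before training) is the
negative control: its decoder should sit at chance. Candidate biomarkers
can be compared head-to-head by training on a single feature column
(`single_feature_embedding`, cross-validated f1), and a
`temperature_scan` utility re-runs the temperature selection at any
scale; the production value 0.1 is fixed and the scan is not re-run in
routine testing.

## Peri-onset analysis and state statistics

Peri-onset curves average each feature over all onsets of a target state
whose full window (default −3 s to +2 s) fits inside the run, without
re-baselining; exclusions are counted. The scalar onset modulation is
mean(+1..+2 s) − mean(−2.5..−1.5 s): because the neural features are
causal 1-s estimates, they lag the underlying state by up to one second,
so windows flush against the onset would mix the two states. Group-level
biomarker contrasts use per-subject per-state feature means and paired
two-sided t-tests for each of the 3 state pairs × 4 biomarkers = 12
comparisons, Holm-adjusted at α = 0.05. Occupancy contrasts between
groups use independent t-tests per state (3 comparisons, Holm).

The four canonical biomarkers are located by naming convention: Hjorth
complexity and HB–LG amplitude on the lesioned (left) hemisphere, Hjorth
mobility and gamma amplitude on the healthy (right) hemisphere.

## Human freezing-of-gait branch

Walkway bouts alternate direction; straight-walk kinematics are
direction-normalized before feature extraction. Features are binned into
1-s portions (per-bin means; a bin spanning a transition takes the
majority label; trailing partial bins dropped). PCA on z-scored bins uses
a deterministic sign convention (largest-magnitude loading positive).
"Top correlated features" are ranked by |point-biserial correlation| with
the gait/FoG indicator (the correlation target is a package choice; the
alternative — correlation with principal components — is available). STN
features are computed at 100 Hz from the 250-Hz LFP after resampling to
200 Hz (the analysis rate must be an integer multiple of the feature
rate). Per patient, the displayed channel is the one maximizing
|mean(beta | FoG) − mean(beta | gait)| over episode means, ties to the
first channel with a logged flag. Significance per feature is a
within-patient, session-constrained label-permutation test on episode
means: the statistic is the difference of label-wise means, the null
permutes episode labels only within each session, and
p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm), Bonferroni-corrected for
the 4 features tested. Arbitrary time masks support artifact exclusion.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the *statistical* structure the analyses assume,
not the biophysics:

* **State sequences** are alternating semi-Markov chains with exponential
  dwells truncated to [0.5 s, run length], covering the run completely.
  Group structure enters through the dwell means — lesioned subjects
  dwell in akinesia for 4 s on average versus 0.8 s for shams — which is
  what produces the occupancy contrast; dwell values are a construction
  choice (only the occupancy ordering is constrained by the phenomenon).
* **Kinematics**: during gait, markers oscillate sinusoidally (4 Hz
  stride, amplitude growing distally) on a 300 mm/s forward drift;
  stationary movement is 2 mm low-passed jitter; akinesia 0.1 mm.
* **Neural channels** are 1/f background (5 µV) plus state-gated
  band-limited components, smoothed over 100 ms at transitions. The
  recipes were calibrated empirically at the 1-s analysis window (the
  mapping from mixture ratios to windowed Hjorth values is not assumed,
  it is measured — see the generator tests): on the lesioned (left)
  hemisphere akinesia gates a strong 20–42 Hz component plus a 2–8 Hz
  component (raising complexity and HB–LG power, lowering mobility),
  while stationary movement mimics akinesia's Hjorth signature with
  shape-matched off-band components (8–16 and 45–70 Hz) so that HB–LG
  power is the *only* left-hemisphere feature separating akinesia from
  stationary movement — mirroring its role as the pathological marker.
  The healthy (right) hemisphere gates gamma during gait and is blind to
  the akinesia/stationary distinction. Broadband filler keeps total
  power approximately equal across states, so signal variance itself
  carries little state information.
* **Human FoG** gates beta (13–20 Hz), a 2–8 Hz component and a mild
  gamma component, giving complexity/beta/gamma up and mobility down
  during FoG (gamma up is deliberately opposite to the rodent gait
  coupling, as observed clinically in the implanted-patient recordings
  this emulates).

Because windows within the first second of a state are intrinsically
ambiguous under causal 1-s features, two named testbeds fix the dwell
structure for specific checks: `embedding_testbed` (balanced 6-s dwells,
30-s runs) for decoding-quality checks, and `recovery_testbed`
(4/4/5-s dwells, 15-s runs, lesioned only) for biomarker-importance and
onset-directionality checks. Passing tests on these cohorts demonstrates
that the estimators, models and statistics recover effects that are
present by construction; they do not establish effect sizes, artifact
robustness, or label noise tolerance on real recordings — real data have
non-stationary backgrounds, correlated marker dropout and imperfect
manual labels that the generator does not model.

## Numerical choices and degenerate inputs

* Hjorth ratios raise a degenerate-signal error on zero-variance input;
  the windowed extractor instead emits 0 for such windows (a constant
  window inside a longer recording is data, not a configuration error).
* Band amplitudes floor the mean periodogram power at 1e-20 before the
  log; bands must lie strictly below Nyquist.
* Sessions whose kinematic file exceeds the neural-implied frame count
  by more than 5 frames (configurable) are discarded with a record, not
  an exception; shorter excesses are trimmed from the file start, where
  spurious frames occur. A kinematic file more than one frame short is
  discarded, since missing frames cannot be reconstructed.
* LDA falls back to analytic shrinkage on ill-conditioned pooled
  covariances (condition number > 1e8) and records having done so.
* The permutation test adds one to numerator and denominator, so the
  smallest achievable p is 1/(n_perm + 1); strata containing a single
  label contribute no label exchanges.
* Ties: KNN votes break toward the nearest neighbor; channel selection
  breaks toward the first channel in insertion order (flagged); PCA
  signs follow the largest-magnitude-loading-positive convention.

## Problem sizes

All routine checks run at desk scale on one CPU: embedding training at
batch 128 × 2,000 iterations (≈1–2 minutes); repeated-seed recovery
checks use the `recovery_testbed` (9 runs × 15 s) with a 0.25-s receptive
field and 600 iterations per fold so that ten seeded replicates complete
in a few minutes; onset-directionality checks use 48 runs × 15 s
(≈40 qualifying onsets). The `paper` profile retains the full-scale
hyperparameters for use with real, full-length datasets.

## Known limitations

* The neural feature panel (Hjorth triple, band amplitudes, burst
  metrics per channel) is a documented subset of the larger panels used
  with full recording rigs; waveform-shape features are out of scope.
* The NumPy encoder is CPU-sized; it makes no attempt to reproduce any
  external contrastive-learning library bit-for-bit, only the algorithm.
* C3D reading requires the optional `ezc3d` dependency; the CSV dialect
  is the canonical, fully tested path.
* Mixed-effects modeling of day-within-subject structure is not
  implemented; day keys are carried through for aggregation only.
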