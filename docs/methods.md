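# Methods

This note documents the models, rules and numerical choices behind
`fusdecode`, and what the synthetic-data experiments do and do not show
about real functional-ultrasound (fUS) recordings.

## Synthetic recordings

The generator (`fusdecode.synthetic`) emulates the statistical structure
a frame-wise behavior decoder assumes in fUS cerebral-blood-volume (CBV)
data:

* **Behavioral states** follow a first-order Markov chain: per-state
  switch probability `1/(dwell_mean_s · frame_rate)`, next state uniform
  among the others, so dwell times are geometric.  Defaults: 20 s mean
  dwell for locomotion bouts, 90 s for sleep/wake episodes (rat NREM/REM
  bouts last minutes).  Recordings can open with a configurable
  initial-state hold (default: 180 s of quiet wake / static), mirroring
  the experimental practice of starting an acquisition in a stable
  condition so the ΔF/F baseline window is well defined.
* **Per-pixel CBV baselines** are log-normal (μ=5, σ=0.5 in log units),
  realizing the strong pixel-to-pixel differences in absolute CBV that
  make ΔF/F normalization necessary.
* **State-dependent signal**: each state drives a configurable ΔF/F
  amplitude per ROI; the drive is convolved with a causal unit-area
  exponential kernel (τ = 1.5 s by default, a gamma kernel is available),
  so a sustained state settles at exactly the configured amplitude while
  transitions are smeared by the 1.5–2 s neurovascular-coupling lag.
  The canonical 4-state map places a tetrahedral ±amp code (every pair of
  states differs in exactly two coordinates) on 3 informative ROIs with
  amplitude 0.10; the remaining ROIs carry no state information.
* **Noise** has two components: iid per-pixel Gaussian noise
  (σ = 0.02–0.05 of baseline; optionally low-pass filtered via
  `noise_tau_s`), which averages away over an ROI, and slow region-wide
  "vasomotion" fluctuations (σ = 0.01 ΔF/F, time constant 1 s, matching
  the ~1 s decorrelation of in-vivo CBV), which do not.  The vasomotion
  term keeps every frame's spatial range anchored by physiological
  fluctuation rather than instrument noise and gives the network a reason
  to pool all informative ROIs rather than a minimal subset.
* **Geometry**: brain mask = ellipse inscribed in the grid; ROI map =
  seeded Voronoi tessellation of the mask, mirrored across the midline
  when the ROI count is even (anatomical maps are bilaterally
  symmetric).
* **Behavior traces** are constructed so the labeling rules can recover
  the ground truth with margin: per-frame speeds in [0.15, 0.30] m/s
  (moving) vs. [0, 0.05] m/s (static) around the 0.1 m/s rule, with the
  running direction flipping before a step would leave the 2.35 m track;
  EMG/acceleration/theta-delta surrogates sit at well-separated levels
  with additive noise (σ = 0.05) below the inter-state gaps.

Everything is deterministic given the config seed; sub-streams (states,
recording, behavior) use fixed seed offsets so each artifact is
individually reproducible.

## Labeling

Locomotion: speed(t) = |Δposition| × frame rate (frame 0 inherits frame
1's value); static below 0.1 m/s, moving above, with a configurable
discard band (degenerate by default) for near-threshold frames, which
are excluded from training/testing but keep their frame indices.

Sleep scoring is deliberately simplified rule-based scoring: wake
whenever EMG ≥ threshold; sleep begins only after EMG has stayed below
threshold for *more than* 10 s (the waiting frames stay wake); within
wake, acceleration separates AW from QW; within sleep, the theta/delta
ratio separates REMS from NREMS.  Thresholds are explicit config values;
`auto_threshold` (midpoint of the robust 5th/95th percentiles) suits the
bimodal synthetic traces.  Ripple power and post-REMS awakening checks
are out of scope — no surrogate signal exists for them.  Note the 10-s
persistence rule systematically labels the first ~10 s of every true
sleep bout as wake; scorer-vs-truth agreement is therefore assessed away
from transitions, and decoding-power experiments use the generator's
ground-truth labels so scorer bias is not conflated with decoder error.

## Preprocessing

Fixed order: ΔF/F (optional) → 2×2 max-pool (pixel mode only) → brain
masking → feature extraction → per-frame scaling → class balancing.

* ΔF/F: per pixel, (x − mean)/mean over the first 180 s (configurable; a
  1-min window also works when mean and SD are estimable).
* Max-pooling drops trailing odd rows/columns; the mask is pooled with
  logical AND (a downsampled pixel is brain only if all four parents
  are).  Masking is applied after downsampling; the order is a
  convention recorded in the provenance sidecar.
* Outside-mask pixels are set to the global minimum of the stack (not
  zero), preserving the stack minimum.
* ROI features are means over full-resolution ROIs, columns in ascending
  label order; ROIs smaller than 20 pixels are merged into the neighbor
  sharing the longest boundary (ties to the lowest label) — an atlas-free
  proxy for "closest in location and function", overridable by an
  explicit merge table.  Cross-acquisition work keeps only ROI names
  present everywhere, in sorted order.
* Per-frame scaling maps each row affinely onto [−1, 1] with exact
  endpoints; rows already spanning the interval pass through unchanged,
  making the map idempotent.  A consequence worth knowing: in frames
  with no differential signal the row range is set by the largest
  fluctuation, so normalization itself spreads class information across
  many inputs (visible in binary-task importance maps).
* Balancing undersamples every class to the minority count, seeded,
  preserving temporal order and original frame indices for the leakage
  analysis.

## Classifier and training

Input → 3 ReLU units → softmax over 2 or 4 classes.  The cost is squared
error on the softmax outputs, J = 1/(2m)[Σ‖p−y‖² + λΣθ²], with λ
applied to weights only (default 0).  Gradients are exact backprop
through the softmax Jacobian; the ReLU subgradient at 0 is taken as 0.
Training is minibatch SGD (batch 8 for sleep, 6 for locomotion),
learning rate α_ep = α₀/(1+ep) read as a closed form — the literal
recursive form α ← α/(1+ep) collapses super-exponentially and is
available behind a flag — with early stopping after validation accuracy
exceeds 0.98 for 50 consecutive epochs, and a hard cap of 10,000 epochs
(the bundled experiments cap at 300, by which point the harmonic
schedule has frozen learning).

Two robustness choices matter in practice.  First, initialization is
Glorot-uniform with zero biases (the recipe does not specify one).
Second, the squared-error-on-softmax landscape has persistent poor
optima in which two states merge (validation accuracy plateaus near
(C−1)/C and the decaying learning rate cannot escape); `fit()` therefore
trains several independent initializations over a small per-problem
learning-rate grid — selected on validation data, as the recipe itself
tunes its learning rate — keeps the best final validation accuracy, and
stops searching once a run clears 0.90.  The grid default (0.5, 0.05)
covers both the fast-converging and the conservative regime.

Splits are stratified 70/15/15; k-fold evaluation (k = 5) assigns every
frame to exactly one test fold and carves validation (15% of the total)
out of each fold's training portion.  Argmax ties break toward the
lowest class index.  Uncertainty is 1 − (p_top1 − p_top2) ∈ [0, 1]; the
un-complemented difference is available as an option.

## Evaluation battery

* Precision = TP/PredPos and Recall = TP/Pos per state; a state never
  predicted has *undefined* precision, reported as missing rather than 0.
* Permutation test: test labels permuted n times (model fixed, no
  retraining), p = (1 + #{perm ≥ observed})/(n + 1) — never exactly 0.
* Transition analysis: fraction of error frames within a window of the
  nearest transition, against a uniform-placement permutation null;
  per-transition-type uncertainty and error-rate profiles aligned on the
  transition frame; and a one-sided Wilcoxon test of per-transition mean
  uncertainty (±2 s) against the away-from-transition mean (frames
  farther than twice the window).
* Uncertainty-rise events: u(t) ≥ (1 + 0.6) × baseline, baseline =
  trailing moving median over 30 s (robust to the spikes being detected;
  a previous-frame mode exists), refractory period = the event window.
* Leakage control: for every frame outside training/validation, distance
  (in frames, with the seconds conversion reported) to the nearest
  training frame; accuracy per distance bin, last bin pooling the tail.
* Transfer: matrix[i, j] = accuracy of animal i's model on animal j's
  ROI-name-aligned dataset (held-out frames on the diagonal);
  "accuracy lost" = mean(diagonal) − mean(off-diagonal).
* Latent cloud: hidden activations as 3-D coordinates with per-class
  centroids and pairwise centroid distances; error frames flagged.

## Importance (HIR)

For each input, 20 replicates (reported in the output) replace its
column with Uniform(−1, 1) draws, weights frozen: overall score =
baseline accuracy − mean randomized accuracy (accumulated as integer
correct-counts so a disconnected input scores exactly 0); per-class
score = mean drop of the class probability over frames whose *true*
label is that class (predicted-label conditioning behind a flag).
Rendered maps put NaN (not 0) outside the mask so "unimportant" and "not
brain" stay distinct; bilateral ROI pairs can be averaged via an
explicit grouping table.  HIR shares the usual caveat of perturbation
importance: redundant inputs split their credit.

## Experiment sizes and calibration

The bundled tests and the acceptance script run on one CPU in minutes;
problem sizes were chosen as the smallest at which each statistical
property is stable: sleep recordings of 1800 s at 1 Hz (22 ROIs, 3
informative, balanced sets of ~650–1300 frames), locomotion recordings
of 900 s at 2.5 Hz, 5-seed sweeps for accuracy, 10 seeds for importance
recovery, 200-permutation tests, and 20 label-shuffled replicates for
null calibration.  The leakage experiments use a deliberately harder
configuration (amplitude 0.04, correlated noise, ~170-frame training
subsets) because the distance-to-training-frame comparison is degenerate
when accuracy saturates; they also omit the initial hold, which would
otherwise confound frame distance with class composition.

## What passing tests do and do not show

The generator reproduces the features the analysis logically depends on
— state-specific regional patterns, hemodynamic smearing, slow
correlated fluctuations, baseline heterogeneity, recoverable labels —
but not real vascular anatomy, atlas registration error, motion
artifacts, scanner drift, micro-states, or the empirical dwell-time
distributions of behavior.  Passing the battery shows the pipeline's
machinery is correct and well calibrated (exact oracles, chance-level
nulls, super-uniform p-values, transition-locked errors, recoverable
importance); it does not certify any particular accuracy on in-vivo
recordings.
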