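# Methods

## The classification procedure

`brainwin` classifies subjects from 4D resting-state fMRI volumes
(X × Y × Z voxels × t time points, repetition time TR) into two diagnostic
groups (1 = ASD, 0 = control). The model treats space and time separately
and fuses them per sliding window:

1. **Spatial encoder.** Each time point's 3D volume X_i is mapped to a
   feature vector F_sp,i ∈ R^d1 by a two-layer 3D-CNN. Each layer applies
   parallel same-padded convolutions at kernel sizes {3, 5, 7}
   (multi-scale), concatenates the branches along the channel axis, applies
   a rectifier and a 2³ max-pool with stride 2. After the last layer the
   feature map is flattened and one fully connected layer projects to d1.
   The encoder sees one frame at a time; there is no temporal mixing.
2. **Temporal encoder.** The series is segmented into k sliding windows of
   length w and stride s, k = ⌊(t − w)/s⌋ + 1, and k is kept odd by
   dropping the final window when necessary (all remaining starts keep the
   j·s formula; with the reference settings t = 50, w = 10, s = 1, k = 41
   is already odd). Each window's per-time-point voxel vectors are fed in
   order to a single-layer LSTM; the final hidden state is the window
   feature F_tem,j ∈ R^d2 (d2 = hidden width).
3. **Fusion and window classification.** F_comb,j = concat(F_tem,j,
   F_sp at the window's first time point j·s) ∈ R^(d1+d2). A
   gradient-boosted decision-tree ensemble (binary cross-entropy
   objective) classifies each fused window vector, giving probability p_j
   and label ŷ_j = [p_j > 0.5].
4. **Subject decision.** ŷ_final = 1 iff Σ_j ŷ_j > k/2 — an unweighted
   majority that cannot tie because k is odd. An even vote length is a
   hard error rather than a tie-break: upstream segmentation guarantees
   odd k, so an even count indicates a bug. A probability-weighted mode
   (mean p_j > 0.5) exists behind `TrainConfig.weighted_vote`, off by
   default.

### Training regime

Boosted trees admit no gradient path into the encoders, so training is
staged:

* **Stage 1** trains both encoders *jointly* with a temporary linear head
  on window-level binary cross-entropy; every window inherits its
  subject's label. Optimizer is Adam at learning rate 1e-3, batch size 32;
  the full-scale default schedule is 50 epochs. `stage1_window_stride`
  subsamples window starts during this stage only (the GBDT stage always
  sees every window) — it trades encoder refinement for time.
* **Stage 2** freezes the encoders, extracts fused features for all
  training windows, and fits the GBDT (defaults: 100 trees, depth 3,
  learning rate 0.1 — the tree hyperparameters are this package's own
  choice).

All windows of a subject stay on one side of every train/test split;
window-level splitting would leak subject identity.

## Preprocessing

In-scope stages, in order: global z-scoring of in-mask intensities →
global signal regression (intercept + in-mask mean series, least squares)
→ 4th-order Butterworth band-pass 0.01–0.1 Hz applied forward-backward
(zero phase; requires t ≥ 28 frames for the filter padding). Framewise
displacement uses the Power convention, FD_i = |Δd_x|+|Δd_y|+|Δd_z| +
r·(|Δα|+|Δβ|+|Δγ|) with head radius r = 50 mm; subjects whose *mean* FD
strictly exceeds 0.2 mm fail QC ("exceeds" — a subject at exactly 0.2 mm
is retained). Spatial registration, slice-timing and motion *correction*
are delegated to external tools; the package consumes already-aligned
volumes and the synthetic generator produces them aligned.

Granularity of intensity normalization is global (one mean/sd over all
in-mask voxels and frames), which removes scanner-level offsets while
preserving spatial contrast; per-voxel temporal z-scoring is available via
`PreprocConfig.per_voxel_normalize`. GSR regresses only the global signal
— no motion-parameter regressors, smoothing, scrubbing or interpolation.

## Synthetic cohorts: what they emulate and what they do not

The generator produces multi-site, class-balanced phantom cohorts.
Inside an ellipsoidal "brain" mask every voxel carries a baseline of 100
units, white Gaussian noise (sd 0.5), a per-voxel slow drift (linear +
half-cosine, fundamental below 0.01 Hz, amplitude 0.3) and a *shared*
background oscillation (amplitude 0.4 at 0.05 Hz, random phase per
subject). A small spherical blob additionally carries a sinusoid whose
frequency is class-coded: 0.03 Hz for controls, 0.08 Hz for cases,
amplitude 1.0, common random phase per subject. Classes therefore differ
*only temporally* — a single frame's intensity distribution is
class-uninformative — which is what makes the spatial-only ablation a
meaningful control. An amplitude-ratio flag switches to statically
separable classes if wanted.

The shared background component is essential for realistic global signal
regression: it dominates the in-mask mean, so GSR removes *it* rather than
the (spatially sparse) class signal. Without it the global signal is
essentially a scaled copy of the blob sinusoid and GSR would cancel the
class structure outright.

Head motion is a per-subject random walk over the six rigid-body
parameters; `inject_motion` applies translations as nearest-voxel integer
shifts with zero fill and rotations exactly (inverse-mapped trilinear
resampling about the volume center). Frame 0 is the reference and is
never resampled.

Per-subject seeds derive from the master seed as
`SeedSequence([master_seed, subject_index])`, so cohorts are reproducible
subject by subject across runs and platforms.

Not modelled: hemodynamic response, physiological noise, EPI distortion,
scanner- or site-specific artifacts, anatomical variability. Passing tests
on these phantoms demonstrates that the pipeline recovers genuinely
temporal class structure end to end under noise, drift, global
fluctuations and motion QC — not that it would reach any particular
accuracy on real multi-site clinical data.

## Numerical and implementation choices

* The 3D-CNN and LSTM are implemented directly on numpy with hand-written
  backward passes. Convolutions are evaluated in the frequency domain
  (batched rfftn products); forward, input-gradient and weight-gradient
  were each verified against finite differences and against
  `scipy.ndimage.correlate`. Arithmetic is float32; preprocessing is
  float64.
* Weight init: He-normal for convolution/linear weights, uniform
  ±1/√hidden for LSTM matrices, zero biases except the LSTM forget gate
  (1.0). All builders take explicit seeds; identical seeds give
  bit-identical parameters.
* The GBDT is LightGBM run single-threaded with `deterministic=True`, so
  an identical master seed reproduces evaluation reports bit for bit.
* The LSTM input per time step is the raw in-mask voxel vector at desk
  scale. At full scale (~10^6 voxels) that is infeasible, so a jointly
  trained linear projection (`TemporalEncoderConfig.input_projection_dim`)
  can be inserted before the recurrence; whether the original design fed
  raw voxel vectors or a reduced representation is not specified anywhere,
  and the projection is this package's explicit choice, recorded in run
  metadata.
* Overlapping windows share no normalization.
* Undefined metrics (zero denominator) are flagged and excluded from fold
  averages instead of being coerced to 0, which would bias small folds.
  Report intervals are 95% Student-t half-widths over fold values.
* Cross-validation folds are subject-level and stratified by class by
  default; 1-based window index j maps to 0-based start (j−1)·s, and all
  interfaces use 0-based half-open ranges.

## Problem sizes used in the shipped experiments

The full-scale configuration (99 × 117 × 95 grids, d1 = 128, 500 hidden
units, 50 epochs) is a config preset. The shipped tests and the
`scripts/acceptance.py` run use the desk-scale study conditions chosen so
the complete pipeline trains on a single CPU in minutes: (16, 16, 12)
voxels × 50 frames at TR 2 s, 40 subjects (20 per class, two sites),
channels_per_kernel 4, d1 = 16, 32 hidden units, 6 stage-1 epochs with
window stride 2. Under 5-fold subject-level cross-validation this
configuration recovers the frequency-coded classes with mean accuracy
≈ 0.95 while a label-permutation control stays at chance; the ablation
replicates the direction that the full spatiotemporal model beats the
spatial-only 3D-CNN + GBDT variant, whose accuracy on temporally coded
classes hovers near 0.5.

## Known limitations

* The vote is unweighted; the optional probability-weighted mode is not
  used in any shipped experiment.
* No probability calibration, site harmonization, RNN/random-forest
  ablation baselines, or statistical machinery for cross-method
  comparison.
* The frequency-coded blob is an explicit stand-in for whatever
  spatiotemporal properties distinguish clinical groups in real data; it
  makes no claim about ASD biology.
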