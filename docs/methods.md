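# Methods

This note documents the models, conventions, numerical choices and known
limitations of the `artvalue` pipeline.

## The value model

Subjective value of stimulus *i* is modelled as a linear sum over feature
values, v_i = Σ_j w_j f_ij with an intercept term (f_i0 = 1).  Ratings on
the 0–3 scale are treated as continuous in all regressions.  Fitting uses
ridge regression under 20-fold cross-validation; feature columns are
z-scored with training-fold statistics only, and the penalty is chosen by
nested CV inside each training fold (log-spaced grid, 15 points over
1e-4…1e3 by default).  Predictive accuracy is the Pearson correlation
between the pooled out-of-fold predictions and the observed ratings;
significance comes from re-running the identical pipeline on
stimulus-label permutations, with p = (1 + #{null ≥ observed}) / (1 + B)
and chance level defined as the null mean.

## The feature bank

All features operate on RGB images in [0,1].  Pinned conventions:

* **Grayscale**: ITU-R BT.601 luma on the 0–255 scale (BT.709 available).
* **Hue statistics**: plain (non-circular) means and modes on hue ∈ [0,1);
  a circular mean is available behind `circular_hue=True`.  HSV (not HSL)
  is the colour space for all mean/mode features.
* **Coordinates**: 0-based, x = column, y = row.  The centre of mass and
  the second/third central coordinate moments are computed in pixel units,
  with a normalised-by-dimension variant (default for cross-image
  modelling, since features are z-scored downstream anyway).
* **Skew**: the raw third central coordinate moment divided by segment
  area — not standardised by variance^1.5.
* **Entropy**: Shannon entropy (bits) of the 256-bin intensity histogram;
  bounded by log2(256) and zero only for a single occupied bin.
* **Symmetry**: the image is cropped to the segment's bounding box
  (including other segments' pixels) and compared with its horizontal or
  vertical mirror by mean squared error of luminance.
* **Intensity bins**: five equal bins tiling 0–255; all five fractions are
  catalog entries and sum to 1.
* **Modes**: 64-bin histograms per HSV channel; the mode is the centre of
  the fullest bin, ties resolved toward the lower bin.
* **Blur**: the highest retained spatial frequency max(|k_x|,|k_y|), with
  k = 2(x − n/2)/n, over components whose unnormalised DFT power of the
  0–255 luminance exceeds 4.  The threshold scale is pinned to that
  (unnormalised) convention and exposed in the function signature.  The
  statistic is invariant to constant offsets (the DC component carries no
  |k|) and decreases under Gaussian smoothing.

### Segmentation backends

* `srm` — statistical region merging over 4-connected pixel pairs sorted
  by colour difference, with the standard merge predicate
  b(R) = g·sqrt(ln(2/δ)/(2Q|R|)); Q is doubled (up to 32 sweeps) until at
  least three non-trivial segments emerge.  A single-colour image cannot
  split and is returned as one segment with `target_not_met=True`.
* `kmeans_lab` — k-means on the A/B chroma channels of CIE LAB (seeded;
  k reduced with a flag when fewer distinct chroma values exist).
  Segments are colour classes, not necessarily connected.
* `graph` — Felzenszwalb–Huttenlocher segmentation with its scale
  parameter bisected per image toward a target count (≈6 by default).
  The feature operators are backend-agnostic; any graph-based segmenter
  could stand behind this name.

Labels are always re-ordered by segment area (descending; ties broken by
earlier raster position), so segment 0 is the largest.

### The catalog

The candidate registry holds 83 entries: 12 graph-backend global
statistics, 13 per-segment statistics × 2 segments for the graph backend,
11 × 2 for SRM, 4 × 2 for k-means, 10 additional global entries
(intensity bins, HSV modes, aspect ratio, entropy), and 5 annotated
high-level attributes.  Only the totals (83 candidates; 79 entering the
low-level selection stage, counting presence-of-a-person with the
low-level pool before its reclassification as high-level) are fixed by
the design; the split of the per-backend local counts inside the
derived block is this package's own reconstruction and is asserted as
registry data in the tests.  Third-segment locals are excluded throughout
(they are nearly collinear with the first two segments).  High-level
values are inputs — annotations or the synthetic generator — never
computed from pixels.

## Shared-feature selection

Features are orthogonalised by sparse PCA (sklearn; `sparsity=0`
dispatches to ordinary PCA so the unpenalised limit is exact).  Selection
is a single joint group lasso over all participants: one group per
component, collecting that component's coefficients across participants,
minimising ½Σ_s‖y_s − X_s b_s‖² + λΣ_j‖B[:,j]‖₂.  The solver is FISTA
with a backtracking line search (factor 0.5) and adaptive restart —
momentum is reset whenever the accelerated step would increase the
objective, and the step is retaken from the current iterate, so the
objective sequence is non-increasing.  Convergence: relative objective
change < 1e-8 or 10,000 iterations.

The penalty is chosen on stimulus-level folds shared across participants
over a log-spaced grid ([1e-4, 1]×λ_max, 30 points by default).  Each λ
is scored by the held-out error of an unpenalised least-squares refit on
its active set (the relaxed-lasso convention) and the one-standard-error
rule picks the final λ.  This choice is deliberate: scoring the shrunken
predictor leaves tiny spurious groups invisible to CV error and ruins
exact support recovery; the relaxed scoring recovers a planted 3-of-10
support in 20/20 seeds at the default conditions.  Penalised scoring and
the min-error rule remain available as options.

Finalisation: components active in fewer than two participants are
discarded; surviving components contribute the features whose |loading|
is ≥ 30% of the component's largest; among any pair with r² > 0.5 on the
selection data the feature later in catalog order is dropped; the
annotated high-level features are appended afterwards (the two-stage
construction: low-level set first, then the annotated attributes).

## Interaction features

Pairwise products of z-scored shared features, grouped low×low (C(13,2) =
78 columns), high×high (C(5,2) = 10) and low×high (13×5 = 65); each group
is reduced by PCA (correlation-scale, since inputs are z-scored) to five
components, matching the number of high-level attributes.  The PCA is fit
on the full stimulus set before any cross-validated regression — this
mirrors the feature-construction-then-regression order of the original
procedure and is flagged here as a known (mild) leakage trade-off.

## Synthetic data

The generator plants exactly the structure the analyses are meant to
detect, so every stage is testable without any external data.

* **Stimuli** — solid-colour rectangles over a background; optional exact
  mirror symmetry (shapes drawn on the left half and reflected); optional
  Gaussian blur applied with periodic (wrap) boundary conditions so that
  the discrete spectrum is attenuated exactly as the Gaussian-blur model
  assumes; shapes kept a margin away from the border so the spectrum has
  no wrap-around leakage.  Intended values of checkable features
  (largest-segment fraction, symmetry class, blur σ) are emitted.
* **Annotations** — noisy linear mixtures of z-scored low-level features
  (noise SD 0.3 by default); presence-of-a-person is a thresholded
  binary.
* **Ratings** — continuous value = z-scored features @ w* plus Gaussian
  noise at signal-to-noise 1 by default, discretised by participant-wise
  population quartiles (balanced 0–3 classes); continuous values and
  planted weights are retained for recovery tests.
* **Design** — 20 runs × 50 trials by default (1000 unique stimuli): 3 s
  stimulus, 3 s decision window with an action at a simulated reaction
  time, 0.5 s feedback, ITI uniform on [2, 9] s, TR 1.12 s, 4 s lead-in
  and 8 s tail per run.
* **BOLD** — per voxel, the stimulus-onset stick regressor is modulated
  by (1−g)·(low mixture) + g·(high mixture) with a voxel-specific g
  jittered around its ROI's planted value; the ROI gradient is
  g = (0.1, 0.3, 0.5, 0.7, 0.9) over five ordered "visual" ROIs, with two
  integrator ROIs at g = 0.5 and one value ROI modulated by the
  continuous rating.  The HRF is the canonical double-gamma (6 s peak
  delay, 16 s undershoot, ratio 6; unit peak), cross-checked against
  nilearn's kernel in a test.  Noise is AR(1) (ρ = 0.3) plus white noise;
  six smooth motion-like nuisance streams are generated and weakly mixed
  into the data to exercise the nuisance interface.  During stimulus
  epochs only, a shared latent white-noise stream is added to the value
  and integrator ROIs (strength 0.8 by default) — the stimulus-locked
  noise correlation that the PPI analysis detects.  Every generator
  records its parameters in a manifest and regenerates bit-identically
  from the same seed.

## Encoding analyses

Design matrices are built per run (convolution never crosses run
boundaries): parametric modulators are mean-centred before convolution,
never serially orthogonalised, and encoded either as onset sticks or 3-s
boxcars; unconvolved nuisance columns and per-run intercepts are
appended; rank deficiency raises an error naming the collinear columns.
Per-trial response amplitudes come from a single GLM holding one onset
stick per trial plus the epoch sticks and nuisance columns (a beta-series
per-trial variant was considered and rejected for desk scale — the joint
GLM is exact in the well-spaced synthetic designs).

Group F tests use the partial F statistic from the diagonal contrast over
the group's columns with (q, residual-df) degrees of freedom, thresholded
at p < 0.001 uncorrected (the cluster-level correction used with
whole-brain data is out of scope here; an optional max-statistic
permutation correction can be layered on the same maps).  Null
calibration is verified at three alphas in the test suite.

The cross-validated route runs a lasso at each voxel (12-fold CV over a
log-spaced penalty grid), computes the sum of squared weights per feature
group, and compares it against a shuffled-label null pooled per ROI (200
shuffles by default; the voxel used for each shuffle cycles through the
ROI).  Significance is statistic > (1−α) quantile of the ROI null.

ROI profiles report the fraction of significant voxels per group in ROI
order; the hierarchy index is the Spearman correlation between ROI order
and the high-minus-low proportion difference (0 when the difference is
constant).

## PPI

The interaction regressor is the elementwise product of the seed
timecourse (mean over value-ROI voxels) and the mean-centred
psychological boxcar (stimulus epochs, or ITI epochs for the control) —
signal-level PPI, no hemodynamic deconvolution; a deconvolved
(Wiener-filter) variant is available behind `deconvolve=True`.
Mean-centring the boxcar separates the interaction from the seed main
effect.  The base model contains boxcar-modulated feature and rating
regressors, the seed and psychological main effects, and nuisance
columns, so surviving interaction effects reflect stimulus-locked noise
coupling.  The t map is thresholded one-sided (positive) at p < 0.001
uncorrected.  Overlap = per-ROI fraction of feature-F-significant voxels
that are also PPI-positive; undefined (NaN) where an ROI has no
feature-significant voxels.

## Layer probe

The reference network is deliberately small: 8 convolutions (3×3, same
padding; 8, 8, 6, 6, 8, 8, 10, 10 channels; 2×2 max-pools after the 2nd,
4th and 6th) and two fully connected layers (24, 12), every layer followed
by ReLU — 10 recordable ReLU points — then a 10-way softmax head whose
probability-weighted average of bin centres yields a rating in [0, 3].
Training: Huber loss (δ = 1), SGD with momentum 0.9, weight decay 5e-4,
batch 100 (20 at desk scale), step decay ×0.1 every 30 epochs; inputs are
scaled so the longest edge fits the canvas and zero-padded.  A VGG-shaped
13-conv + 2-FC configuration is constructible from the same config class
but is not trained in the test suite.  The implementation is pure numpy
(im2col convolutions with full backprop), which keeps the probe analyses
dependency-light and deterministic.

Depth matters for the statistics: with L layers the layer-label
permutation p-value cannot fall below 1/(L!+1), so at least 7 ReLU points
are needed for p < 0.001 to be attainable — and step-like decoding
profiles need several layers on each side of the step before the observed
slope beats enough permutations.  The 10-layer default gives graded
profiles with comfortable headroom.

Training a tiny network from a random init occasionally sticks in a poor
optimum (training-set correlation near zero); the probe pipeline then
re-initialises and retrains, up to three attempts, keeping the best
training fit.  The criterion uses the training set only.

Decoding: within each of 10 folds, PCA is fit on the training
activations only (centring, covariance scale — per-unit variance scaling
is deliberately avoided because near-silent ReLU units produce unbounded
z-scores on held-out data) and components are kept up to 80% of training
variance; ridge regression (grid 1e-3…1e3, 13 points) decodes continuous
features, logistic regression categorical ones (accuracy, AUC and F1 on
pooled predictions; folds stratified).  For categorical features the AUC
is the slope metric: it varies smoothly with the decision scores where
thresholded accuracy is step-like, and the slope sign is the same across
the three metrics.  Classification: least-squares
slope of score against layer index, permutation of layer labels (10,000
draws), high if significantly positive at p < 0.001, low if significantly
negative, else unclassified.

The planted oracle trains the network on procedural stimuli whose rating
follows layout properties; the shallow probe feature is a pixel statistic
irrelevant to the rating (mean blue channel) and the deep probe feature
is a threshold of the trained readout.  With random untrained weights the
deep feature loses its high-level signature, mirroring the trained-vs-
untrained control.

## Problem sizes

The test suite and the acceptance script run the BOLD analyses on 5
feature ROIs + 2 integrator ROIs + 1 value ROI at 20 voxels each, 4 runs
× 25 trials; the behavioural stage uses 120 extracted stimuli at 48×48
px and 6 participants; the probe uses 160 stimuli at 16×16 px.  These
sizes were chosen so each suite completes in minutes on a single CPU
while keeping every recovery property comfortably detectable; the
generators accept the full-scale settings (20×50 design, larger images,
more voxels) unchanged.

## Limitations

* The synthetic stimuli are piecewise-constant compositions: they exercise
  the segmentation and feature code exactly, but they do not reproduce the
  texture, perspective or semantic content of real paintings, so passing
  tests certify the estimators' recovery properties, not claims about real
  art or real brains.
* High-level annotations are linear-plus-noise functions of low-level
  features by construction; real annotated attributes are only partially
  predictable from low-level features.
* BOLD noise is AR(1)+white with smooth nuisance streams; no physiological
  noise, motion artifacts or spatial autocorrelation are modelled, and no
  spatial normalisation/smoothing is implemented.
* PPI is correlational and says nothing about coupling direction.
* At desk scale the probe network's representations vary noticeably from
  init to init: occasionally a well-fitting network still discards the
  shallow probe statistic immediately after the first layer, which turns
  its decoding profile into a step that the layer-permutation test cannot
  call at p < 0.001.  The restart rule removes failed optimisations, not
  this representational variability; rates reported over seeds reflect it.
* Hue means are non-circular by default, as in the source feature set; for
  hue distributions that straddle the wrap point the circular option is
  more appropriate.
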