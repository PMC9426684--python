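# Methods

This note documents the models, conventions and design choices behind
`cinescar`, in the spirit of a methods appendix: what is computed, under
which assumptions, and which defaults matter.

## Problem setting

After myocardial infarction (MI), scar tissue is visualised clinically with
late gadolinium enhancement (LGE) imaging, which requires a contrast agent.
Contrast-free cine short-axis (SAX) acquisitions, however, already carry
indirect evidence of scar: reduced regional contraction, subtle signal
changes, and altered myocardial texture.  The package implements a pipeline
that (i) prepares LGE-derived ground truth in cine coordinates, (ii)
engineers motion and texture features from the cine frames alone, and (iii)
trains classifiers that predict, from contrast-free cine, whether the
corresponding LGE image would show scar.  Because clinical data cannot ship
with the code, every component is exercised on a synthetic phantom whose
ground truth is known exactly.

## Synthetic phantom (`cinescar.phantom`)

One study is a single short-axis slice location: a cine sequence of up to 32
frames with trigger times (TT, ms after the ECG R wave), per-frame label
masks (0 background, 1 myocardium, 2 LV cavity), and one LGE record with a
known affine misalignment and a ground-truth mask that additionally labels
scar (3).

**Motion model.**  Material points move radially about the slice centre.  A
point at reference radius `r` and angle `θ` sits at radius
`r·c(r, θ, t)` in frame `t`, with

```
c(r, θ, t) = 1 − A · g(θ) · s(t) · w(r)
s(t)       = sin²(π t / (T − 1))
```

where `A` is the contraction amplitude (default 0.25), `g(θ)` equals the
scar contraction factor inside the scar sector (cosine-tapered over 10°) and
1 elsewhere, and `w(r)` holds the motion at full strength out to the
epicardium and fades it to zero 8 px beyond.  `s(0) = s(T−1) = 0`, so the
cycle closes exactly.  Frames are rendered by sampling a fixed per-study
reference scene through the *inverse* of this map (inverted by bisection),
which makes brightness constancy hold by construction — the optical-flow
stage therefore measures true motion — and the per-frame masks come from the
same inverse map, so masks and images are exactly consistent.

**Scene content.**  Base intensity levels differ by modality (cine: bright
blood pool, mid-grey myocardium; LGE: dark myocardium, hyperintense scar at
`myo + scar_intensity_delta`).  Both modalities share one smooth random
texture field (Gaussian-filtered white noise, σ = 2 px, normalised to unit
standard deviation and scaled to amplitude 0.15) because they image the same
tissue.  The scene also contains static asymmetric extra-cardiac structure —
a bright chest-wall band and a dark lung field.  This is not decoration: a
purely annular phantom is rotationally symmetric, which makes the rotation
component of affine registration unidentifiable; real thoracic anatomy
provides exactly this angular structure.  Additive Gaussian noise (default
SD 0.03, clipped to non-negative intensities) is drawn independently per
frame and modality.

**LGE acquisition.**  The LGE image is rendered at a late-cycle phase (80%
of the cycle, mimicking diastolic acquisition) and its trigger time falls
strictly between two cine trigger times, so trigger-time matching is
non-trivial.  The configured affine misalignment (translation, rotation,
anisotropic scale, shear) is applied to the image (linear interpolation) and
mask (nearest neighbour) and recorded as ground truth.

**Cohorts.**  `generate_cohort` jitters geometry (cavity radius ±1 px, wall
thickness ±0.75 px), contraction amplitude (±0.01), noise (±20%), scar
sector (start uniform over the circle, extent 80–140°, contraction factor
0.25–0.45) and misalignment per study, all deterministically from one seed.
The inter-subject jitters are deliberately kept small relative to the scar
effect: the weakest designed scar (80° sector at factor 0.45) still reduces
the peak global area-change rate by ~12%, versus ±4% amplitude spread and
±20% myocardial-area spread between subjects.  The phantom is *designed* so
that scar discrimination is achievable from the engineered features — even
by a single axis-aligned decision tree, whose splits cannot normalise one
feature by another and therefore need a univariately visible effect.  What
passing the cohort benchmark shows is that the pipeline extracts and
classifies the designed signal correctly; it does not show that real cine
MR is separable at these accuracies (the clinical problem is far harder:
real contractile variability between subjects is larger, scar effects are
subtler, and anatomy is not annular).

## Ground-truth preparation (`cinescar.prep`)

1. **Trigger-time matching** selects the cine frame with the smallest
   |TT − TT_LGE|, ties toward the earlier frame.
2. **Mutual-information affine registration** maps the LGE image onto the
   matched cine frame.  The metric is mutual information in nats from the
   joint intensity histogram (50 bins per axis, each image binned over its
   own range; images with fewer than two distinct values define MI = 0).
   The transform model is translation + rotation + per-axis log-scale +
   shear about the image centre, in 0-based (row, col) coordinates with
   counter-clockwise-positive rotation; parameters are a *content* transform
   (applying them moves image content), and resampling pulls intensities
   through the inverse map.  The optimiser is a (1+1) evolutionary strategy:
   Gaussian perturbations with per-parameter steps (1 px, 1°, 0.01 for
   log-scale/shear) whose radius grows by 1.05 on acceptance and shrinks by
   1.05^(−1/4) on rejection, accepting only improvements.  It runs coarse to
   fine over a 3-level pyramid (shrink 4/2/1 with smoothing σ 2/1/0 and
   120/200/300 iterations), after a deterministic initialisation that
   evaluates a coarse translation×rotation grid (±12 px step 3, ±18° step 3,
   plus an intensity-centroid candidate) at the coarsest level.  The
   pyramid and the exhaustive coarse sweep are needed in practice: a
   single-level ES from identity stalls on rotation and occasionally locks
   onto far-off local optima.  The result is best-so-far: if the final MI is
   below the unregistered MI, identity is returned, so MI never decreases.
   On phantom pairs with |t| ≤ 10 px, |rot| ≤ 15°, scale ∈ [0.9, 1.1] the
   recovery error is ~0.15 px / 0.25° median.
3. **Stacking** pads with zero frames (appended) or truncates to exactly 32.
4. **Alignment QC** scores each registered pair with a normalised
   cross-correlation over the myocardial band (myocardium dilated by 3 px,
   scar-labelled pixels excluded since they enhance only in LGE), after
   removing each image's radially symmetric intensity profile about the
   whole-heart centroid.  The radial-profile removal makes the score
   sensitive to residual rotation even for a near-annular heart; the raw
   band NCC is not.  Pass threshold 0.5 (configurable).  QC only flags —
   nothing is deleted.

## Losses and metrics (`cinescar.metrics`)

The per-channel Dice similarity is `(2·Σyŷ + ε)/(Σy + Σŷ + ε)` with
ε = 10⁻⁶; on hard masks it equals the set-overlap form `2|A∩B|/(|A|+|B|)`,
and the smoothing defines the empty-channel case as a perfect match (0/0 →
1) rather than NaN — empty scar channels are the norm, and a model that
correctly predicts "no scar" should not be penalised.  The channel-weighted
Dice loss is `Σᵢ βᵢ(1 − DSCᵢ)` with default β = (0.15, 0.25, 0.25, 0.35)
for (background, myocardium, cavity, scar) — most weight on the scar.

Class weights for imbalanced binary classification are
`λᵢ = (1/kᵢ)·(N/C)`; for a 506-sample training set split 336/170 this gives
0.753 and 1.488 (full precision is stored; three decimals are display only).
The weighted cross-entropy multiplies each sample's log-likelihood by the
weight of its true class and averages; probabilities are clipped at 10⁻⁷; a
scalar sigmoid output p is expanded to the pair (1−p, p) so the one-hot
inner product is always well defined.  With unit weights it reduces exactly
to mean cross-entropy.

Classification reports expose the confusion matrix, precision, recall, F1
and accuracy with zero-denominator cases reported as 0 plus a flag.
`cv_roc_auc` runs stratified k-fold (default 10) cross-validation, computes
a ROC per held-out fold from decision scores, interpolates onto a common
101-point FPR grid and reports mean AUC ± SD; folds are reduced with a
warning when a class is smaller than the fold count.

## Motion features (`cinescar.motion`)

Dense Lucas–Kanade optical flow solves, per pixel, the 2×2 structure-tensor
normal equations accumulated over a local window — products of central-
difference spatial gradients and the plain frame difference are smoothed by
a 5×5 Gaussian (σ = 3) and summed over an 8×8 box.  Pixels whose smallest
structure-tensor eigenvalue is below 10⁻³ (the aperture problem; flat
regions) get zero velocity and a low-confidence flag.  The solver is the
standard single-level formulation and is accurate to ≲0.1 px for
displacements up to ~2 px; larger motion would need a pyramidal variant,
which is out of scope.

Frame pairs follow the canonical enumeration `(i, min(i+k, T−1))` for
`i = 0, k, 2k, …` while `i ≤ T−2`: the unique simple rule that yields 11
displacement maps for 32 frames at the default skip interval k = 3.  Raw LK
displacements are converted to velocities per millisecond with the actual
trigger-time difference of the pair (phantom spacing is uniform; real
acquisitions need not be), and the displacement magnitude is `r = |v|·k·Δt`.
The magnitude is Euclidean `√(vx²+vy²)`; a literal component sum is
available behind `magnitude="sum"` for strict reproduction of the printed
formula, but the Euclidean form is the physically meaningful one and is the
default.  Each of the 11 maps is compressed by PCA (8 components per map
position, fitted on the training split only to avoid leakage) and the
projections concatenate into the flow feature row.

The rate of myocardial area change uses the same pair enumeration:
`aᵢ = (A_{i+k} − A_i)/(k·Δt)` with `A` the myocardium pixel count times the
pixel area; pairs lacking the myocardium label are flagged NaN rather than
dropped.

## Radiomics (`cinescar.radiomics`)

Images are resampled in-plane to 1.9 mm isotropic spacing by separable area
(box) interpolation — exact conservation of integrated intensity for
interior content; masks by nearest-neighbour at output pixel centres.  "1D
area interpolation" is read as this separable box filter.  Intensities are
clipped to the 1–99 percentile window of the masked pixels and quantised to
256 levels (rounding to nearest level); a degenerate window maps everything
to level 0 with a flag.

Features are extracted at three frames — end-diastole (argmax cavity area),
end-systole (argmin) and the middle frame `floor((ED+ES)/2)` (rounding
toward ED; the convention is arbitrary and documented) — on the myocardium
mask only, 18 features per frame:

* **shape (5)**: major/minor axis length from the 4·√eigenvalue convention
  on the second central moments of foreground pixel coordinates; maximum
  diameter as the largest pairwise distance between boundary (convex-hull)
  pixel centres; Crofton perimeter (4 directions — the weighted-chain
  estimator was rejected because it leaves a disk's sphericity at the edge
  of its expected band, and it is undefined for a single pixel); sphericity
  `2√(πA)/P`.
* **first order (9)**: energy, total energy (energy × pixel area), mean,
  median, maximum, range, RMS, 10th and 90th percentile (linear
  interpolation between closest ranks).
* **GLRLM texture (4)**: gray-level non-uniformity, run-length
  non-uniformity, its normalised variant and run entropy (log₂), from
  run-length matrices of maximal equal-level runs inside the mask along
  0°/45°/90°/135°, averaged over the four directions.  Leaving the mask
  breaks a run; `Σ l·P(g,l)` equals the masked pixel count per direction.

Feature selection is two-stage, both sklearn-style transformers fitted on
training data only: a greedy redundancy filter in canonical sorted-name
order (a column is dropped iff |Pearson r| > 0.9 with an already-kept
column; constant columns drop with reason "constant") and a significance
filter keeping features whose point-biserial correlation with the binary
outcome has p < 0.001 (t distribution, n−2 df, no multiplicity correction —
matching the stated raw threshold).

## Classical models (`cinescar.classical`)

Splits use floor-remainder sizing (non-training partitions get
`floor(f·N)`, training the remainder — 722 at 70/15/15 gives 506/108/108),
a seeded shuffle, and stratification by default (exposed as a flag; it
stabilises small synthetic cohorts).  Standardisation is z-scoring with
training-partition statistics; constant features map to 0 and are flagged.
The SVM uses an RBF kernel with C = 1 and gamma = 1/(d·Var); the decision
tree uses Gini impurity and unlimited depth — hyperparameters are
deliberately plain defaults, all overridable.  (A cross-validated depth/C
grid was evaluated and rejected: at ~128 training samples the CV noise
selected worse settings than the defaults.)  Permutation importance shuffles
each feature 10 times on the evaluation partition and reports the mean and
SD of the accuracy drop.

## Deep components (`cinescar.nn`)

The layers (convolution, batch normalisation, ReLU, 2×2 max pooling,
nearest-neighbour upsampling, dropout, dense, sigmoid, channel softmax) are
implemented in NumPy with explicit forward/backward passes, verified against
finite differences.  The UNet is the standard encoder–decoder with skip
concatenation; the default configuration is scaled down (8 base filters,
depth 3, 64 px frames, 32 input channels = the cine frames) so it trains on
a CPU in seconds, with 30% dropout in the three up-sampling convolutional
blocks and a 4-channel softmax head.  The full-scale topology is the same
graph with more filters and 224 px inputs; training it is out of scope here.

The ResNet-50 builder enumerates the canonical bottleneck topology
([3, 4, 6, 3] stages, projection shortcuts, 7×7/64 stem over the 32-channel
input, global average pooling into one sigmoid unit) and computes parameter
counts from the enumeration — convolutions carry biases and batch-norm
moving statistics count as non-trainable parameters, giving 23,680,705
total / 23,627,585 trainable at 32 input channels.  It is a structural
description for parameter accounting; phantom-scale training uses the UNet
and the classical models.

Training uses Adam (default, lr 10⁻³) or RMSProp (10⁻⁴), a learning rate
held for 5 epochs then multiplied by exp(−0.1) per epoch ("decreasing
exponentially at a rate of −0.1", read as a per-epoch factor), batch size
32, and early stopping after 30 epochs without improvement of the monitored
loss (training loss by default, as literally specified; a validation mode is
available), restoring the best epoch's weights.  Class weights for the
weighted cross-entropy are recomputed from the actual training-partition
counts, never hard-coded.  Augmentation rotates image and mask together
(rotation uniform in ±60°, masks nearest-neighbour) and normalises each
image to (0, 1) by its 1–99 percentile window.

## Pipeline and reproducibility (`cinescar.pipeline`, CLI)

`run_pipeline` chains simulate → prep (registration + QC) → features →
train-split feature selection → standardise → SVM/DT → reports.  Feature
sets {flow, area, radiomics} can be combined freely (the three ablation
configurations).  Every stage derives its seed deterministically from the
global seed via a name-hash, so reruns reproduce the feature table bit for
bit; artifacts carry the config hash.  The default cohort is 80 scar + 80
healthy studies at 64 px and 32 frames — sizes chosen so a full 5-seed
benchmark runs in minutes on one CPU while keeping ≥ 30 test samples per
split.  The `cinescar` CLI exposes simulate/prep/features/classify/
train-dl/evaluate/run-all over the same library calls.

## Known limitations

* The phantom has no through-plane motion, no right ventricle, no bias
  field, no k-space/coil simulation; its noise is Gaussian rather than
  Rician; and its scar effect is designed to be recoverable (see above).
* Registration is 2D affine only; deformable registration is out of scope.
* Single-level Lucas–Kanade limits reliable flow to small displacements.
* The GLRLM implementation quantises before masking-aware run extraction;
  features are averaged (not merged) across directions.
* The ResNet-50 builder counts parameters but does not train; the NumPy
  UNet is CPU-scale and not intended for clinical-size images.
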