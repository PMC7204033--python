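# Methods

## Problem and model

After surgical resection of a glioblastoma, the resection cavity (RC) is a
core component of the radiotherapy gross tumor volume and must be contoured
on post-operative multimodal MRI (T1w, T1w-gadolinium, T2w, FLAIR).  The
package automates this delineation with a 2D fully-convolutional densely
connected encoder–decoder applied slice-wise along the three orthogonal
planes (a 2.5D scheme), and ships the full experimental harness around it:
intensity preprocessing, multi-rater reference fusion, cross-validation
training, tri-planar inference, and a Dice/volume evaluation suite — all
exercisable end to end on synthetic phantoms.

### Network

The architecture is a DenseNet-style encoder–decoder with four
contraction–expansion levels by default:

- **stem**: 3×3 convolution (4 → 48 channels) + dropout;
- **dense unit**: batch-norm → ReLU → 3×3 convolution → dropout;
- **dense block**: 4 densely connected units with growth rate 12, so each
  block concatenates 48 channels onto its input;
- **transition-down**: a channel-preserving dense unit (C → C, no
  concatenation) followed by 2×2 max pooling with floor semantics;
- **transition-up**: bilinear interpolation to the exact stored skip extent
  followed by a 3×3 convolution compressing to 48 channels;
- **head**: 1×1 convolution to 2 channels + softmax (foreground =
  cavity, background).

With the defaults the encoder channel trace is 48 → 96 → 144 → 192 → 240 →
288 and the decoder trace 336 → 288 → 240 → 192 (each decoder stage is
48 transition-up channels + the skip + 48 dense-block channels), for
2,390,450 parameters.  The growth rate 12 follows from 48 channels per
4-unit block; the channel-preserving transition-down convolution is the
unique reading under which that trace is reachable.  Because pooling floors
odd extents (25 → 12) and upsampling targets the stored skip sizes, any
input with sides ≥ 2^levels is processed at its native size, with the
output extent equal to the input extent.

The layers are implemented directly in numpy (channels-last storage;
convolutions evaluated as nine shifted GEMMs over the padded input), with
explicit backward passes verified against finite differences to ~1e-8
relative error.  Weight initialization is rectifier-scaled (He) from a
seedable generator.  The stem follows the block table literally
(convolution + dropout, no normalization).

### Training protocol

Batches of 16 two-dimensional slices of random orientation (axial, coronal,
sagittal) are drawn uniformly over (case, orientation, slice), restricted
to slices that intersect the brain foreground — background-only slices
carry no gradient under plain cross-entropy.  Mixed-size slices in a batch
are zero-padded to the batch maximum.  The pixel-wise cross-entropy loss is
minimized with Adam (β₁ = 0.9, β₂ = 0.999) at the default learning rate
1e-4; no class weighting, augmentation, or schedule is used.  The stopping
rule is a fixed step count (`epochs × steps_per_epoch`).  Training is
reproducible: the sampling and dropout streams derive from the config seed.

### Preprocessing

Inputs are assumed rigidly co-registered onto one grid and skull-stripped
(zero-filled background); the package validates grid conformance (affine
agreement to 1e-3 mm) and never resamples.  Each channel is z-scored to
mean 0, sd 1 over the brain support (union of nonzero voxels across
channels), using the population standard deviation so normalization is
exactly idempotent; out-of-mask voxels are forced to 0.  Restricting the
statistics to the brain keeps the zeroed background from dominating μ and σ.

### Reference fusion

The reference segmentation is the per-voxel strict majority vote over the
expert masks (2 of 3 raters).  For even rater counts a tie defaults to
background; an `include_ties` flag flips that.  Label files are accepted as
float dialects: values within 1e-3 of 0 or 1 are rounded, anything else is
rejected to keep interpolated masks out of the pipeline.

### Inference and decision rule

At test time every slice along each of the three orientations is forwarded
in evaluation mode (dropout off, running batch-norm statistics — hence
deterministic), the per-orientation foreground-probability volumes are
averaged voxel-wise, and the average is thresholded at 0.5 (equivalently,
argmax of the averaged two-class output).  The threshold is exposed because
the decision rule after averaging is a free choice; a binary 2-of-3 vote
over the per-orientation masks is available behind a flag as the
alternative reading of "averaging the three predictions".  No morphological
postprocessing is applied.

### Evaluation and statistics

Per case and pairing (automatic vs each rater, rater vs rater, automatic vs
fused reference) the package reports the Dice coefficient
2|A∩B|/(|A|+|B|), the signed relative volume error (V_a − V_ref)/V_ref
(negative = underestimation), and absolute volumes in cm³; summaries use
medians and IQRs (Q3 − Q1, linear-interpolation quantiles).  Dice between
two empty masks is defined as 1 (agreement on emptiness), empty vs
non-empty as 0; the relative volume error is undefined for an empty
reference.  Group comparison runs Shapiro-Wilk normality checks per group,
a Kruskal-Wallis omnibus test, and — only when the omnibus p < α (0.05) —
pairwise unpaired Wilcoxon rank-sum tests.  The test statistics come from
scipy.stats; the module's contribution is the gated workflow and the report
shape.  If every value in every group is identical the omnibus statistic is
0 and pairwise testing is skipped.

## Synthetic phantoms

Clinical post-operative cohorts of this kind are private, so the package
generates 4-channel phantoms that emulate the *contrast structure* of the
task rather than MR physics:

- an ellipsoidal brain (zero-filled exterior, as after skull-stripping)
  with two para-midline ventricles;
- one irregular ellipsoidal cavity (semi-axes 12–22 mm, smooth random
  boundary perturbation), bright on T2w and dark on T1w;
- optional air pockets (dark on all channels, p = 0.5) and blood products
  (bright on T1w, p = 0.5) inside the cavity; the reference label includes
  both subregions, matching the clinical cavity definition;
- a smooth multiplicative bias field (amplitude 0.10) and additive Gaussian
  noise (sd 6 on tissue means of order 100), the documented failure modes
  of intensity-based segmentation;
- ventricles share the cavity's T1/T2 signature but are dark on FLAIR —
  the multimodal cue that makes them resolvable confounders and motivates
  feeding all four channels.

The default grid is 64³ at 2 mm so a full train-and-predict cycle runs on
one CPU in minutes.  Simulated raters warp the reference with a smooth
random displacement field plus occasional one-voxel erosion/dilation and
can exclude the air/blood subregions.  The default displacement sd of
1.5 mm was calibrated over 20 seeds to a median pairwise Dice of ≈0.84,
inside the 0.80–0.90 band that human experts reach on this task.

What the phantoms do **not** model: real anatomy and its deformation after
surgery, edema and infiltration, acquisition physics (TR/TE, partial
volume), registration error, or rater biases correlated with image content.
Passing the phantom experiments therefore demonstrates that the pipeline's
mechanics — preprocessing, fusion, optimization, tri-planar inference,
metrics — work and that the network can learn a multimodal intensity rule
in the presence of bias fields, noise, and confounders; it does not certify
clinical accuracy.

## Scaled-down experiment sizes

The learnability experiments use a reduced network (levels = 2, stem 16,
growth 4, 2 units per block; ~33k parameters) and learning rate 1e-3 —
appropriate for the small, high-contrast phantom task, while the library
defaults (full architecture, lr 1e-4) describe the clinical-scale
protocol.  The shipped experiments are: a 3-fold cross-validation on a
6-case 64³ cohort (120 training steps per fold) plus two single-fold runs
at further seeds; an overfit check (2 clean-reference 48³ cases, 200
steps, 3 seeds); and a bit-level reproducibility check (two identical
micro cross-validations must produce byte-identical metrics tables).

## Numerical choices and edge cases

- Geometry comparisons: absolute tolerance 1e-3 mm on spacings and affines;
  voxel indices 0-based.
- Normalization: population (n) standard deviation; constant channels
  raise a degenerate-input error.
- Binarization: foreground iff probability ≥ threshold (0.5 default).
- Pooling floors odd extents; bilinear resize uses half-pixel centers and
  its backward pass is the exact transpose of the forward map.
- Cross-validation: cases are shuffled by a seeded generator; test-set
  sizes differ by at most one; exactly one fold is flagged for
  hyperparameter tuning.
- One global seed fans out to per-stage, per-fold seeds through numpy's
  `SeedSequence`, so every stage is independently reproducible.
- Non-finite training loss raises an error naming the step.

## Known limitations

- The 2D network sees one slice at a time; cross-slice consistency comes
  only from tri-planar averaging.
- CPU-only numpy training is practical at phantom scale; clinical-scale
  training (256² slices, tens of thousands of steps) would need a GPU
  framework behind the same module surface.
- The statistical chain assumes independent values within groups; pooled
  per-case pairings are not strictly independent.  `compare_groups` accepts
  any grouping, so callers can compare pooled automatic-vs-rater against
  rater-vs-rater values (as the CLI does) or individual pairings.
- Majority-vote fusion is purely voxel-wise; no probabilistic fusion
  (e.g. STAPLE) is provided.
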