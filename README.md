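# cavseg

Automated delineation of the **brain resection cavity** (RC) on
post-operative multimodal MRI.  After glioblastoma surgery the cavity is a
core component of the radiotherapy gross tumor volume, and contouring it
by hand on T1w / T1w-gadolinium / T2w / FLAIR takes experts ~20 minutes
per case with substantial inter-rater variability.  `cavseg` implements a
fully automatic alternative — a densely connected fully-convolutional
encoder–decoder applied slice-wise in the three orthogonal planes — along
with everything needed to train and evaluate it: intensity preprocessing,
majority-vote fusion of expert contours, a cross-validation harness,
Dice/volume metrics with the standard non-parametric statistics, and a
synthetic phantom generator that stands in for private clinical cohorts.

## The method in brief

**Network.** A DenseNet-style 2D encoder–decoder with four
contraction–expansion levels.  Each dense block holds four units
(batch-norm → ReLU → 3×3 conv → dropout, growth rate 12, dropout p = 0.2);
transition-down is a channel-preserving dense unit plus 2×2 max pooling,
transition-up a bilinear upsampling plus a 3×3 convolution.  The encoder
channel trace is 48 → 96 → 144 → 192 → 240 → 288, the decoder
336 → 288 → 240 → 192, ending in a 1×1 convolution and softmax over
{cavity, background} (2,390,450 parameters).  The layers, backward passes
and the Adam optimizer are implemented directly in numpy and
gradient-checked against finite differences.

**Training.** Batches of 16 slices of random orientation (axial, coronal,
sagittal) drawn from normalized studies; pixel-wise cross-entropy
minimized by Adam at learning rate 1e-4.

**Inference (2.5D).** The network segments every slice along each of the
three orientations; the three foreground-probability volumes are averaged
voxel-wise and thresholded at 0.5.

**Reference.** A voxel enters the reference segmentation when a strict
majority of the experts marked it (2 of 3 raters).

**Metrics.** Dice coefficient 2|A∩B|/(|A|+|B|), signed relative volume
error (negative = the automatic contour underestimates), absolute volume
in cm³; Shapiro-Wilk → Kruskal-Wallis → (gated) Wilcoxon rank-sum
statistics across pairings.

## Worked example

Generate a 6-case synthetic cohort (three simulated raters per case) and
run the full experimental loop — per fold: split → train → predict →
evaluate — with a reduced architecture suitable for a laptop CPU:

```bash
cavseg simulate --cases 6 --seed 0 --out cohort/
cat > reduced.yaml <<EOF
architecture:
  stem_channels: 16
  growth_rate: 4
  units_per_block: 2
  levels: 2
training:
  learning_rate: 0.001
  epochs: 1
  steps_per_epoch: 120
EOF
cavseg crossval --manifest cohort/cohort.txt --config reduced.yaml \
                --k 3 --seed 0 --out results/
```

which prints:

```
fold 0: train n=4, test n=2
fold 1: train n=4, test n=2
fold 2: train n=4, test n=2
metrics written: results/metrics.csv (median auto-reference Dice 0.923)
```

`results/metrics.csv` holds one row per case and pairing; for `case001`:

| case_id | pairing        | dice | rel_vol_err | vol_a | vol_b |
|---------|----------------|------|-------------|-------|-------|
| case001 | auto-rater1    | 0.88 | −0.15       | 24.0  | 28.3  |
| case001 | rater1-rater2  | 0.66 | +1.03       | 28.3  | 14.0  |
| case001 | auto-reference | 0.92 | +0.06       | 24.0  | 22.5  |

Read it as: the automatic mask of `case001` (a held-out case — each fold's
network never saw its test cases) overlaps the fused expert reference with
Dice 0.92 and is 6% larger; on this case the two simulated raters happen to
disagree strongly (Dice 0.66 — rater2 under-contoured), which is exactly
the situation majority-vote fusion absorbs.  Across the cohort the summary
gives median auto-reference Dice 0.923 (IQR 0.011) against a median
inter-rater Dice of ≈0.86.  `results/summary.csv` aggregates medians and IQRs
per pairing, `results/stats.json` holds the gated statistical comparison
(automatic-vs-rater pooled against rater-vs-rater), and
`results/provenance.json` records the config hash and seed that make the
run bit-for-bit reproducible.

Every stage is also available as a library call (`generate_cohort`,
`zscore_normalize`, `majority_vote`, `build_network`, `train`,
`segment_study`, `evaluate_cohort`, `compare_groups`) and as individual
CLI subcommands (`simulate`, `fuse`, `split`, `train`, `predict`,
`evaluate`).

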