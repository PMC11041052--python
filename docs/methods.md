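# Methods

## Problem and pipeline

The package detects pancreatic cystic lesions (PCLs) in 3D abdominal CT by
semantic segmentation into background / pancreas / cyst followed by
rule-based false-positive filtering and study-level scoring. A study counts
as *detected* when at least one predicted cyst component survives filtering
and (for cases) overlaps the ground-truth cyst mask.

Stages, in order: soft-tissue windowing → central crop → patch-based
attention-gate U-Net → test-time-augmentation merge → uncrop → abdomen-mask,
pancreas-contact and minimum-size filters → per-study outcome and cohort
metrics.

## Volumes and conventions

All volumes are NIfTI, reoriented to RAS on load; the axial plane is the
first two array axes, the slice axis the third; indexing is 0-based. Labels
are 0 = background, 1 = pancreas, 2 = cyst.

## Preprocessing

The pancreas and most cystic lesions are centred near 50 HU, so intensities
are clipped to **50 ± 100 HU** and mapped linearly to [0, 1]. The output
range is a package choice (the window itself is the standard one); a linear
rescale keeps the map monotone and makes network inputs scale-free.
The central crop keeps a **240×240** in-plane window (identity at phantom
scale, where we use `crop_size` = grid size); odd remainders leave the extra
voxel on the high side — an arbitrary but fixed, tested rule. Inputs smaller
than the crop are an error, never padded.

## Network

AGNet is a U-Net: per scale two 3×3(×3) convolutions, each followed by
instance normalization and ReLU; factor-2 max-pooling between encoder
scales; factor-2 linear (trilinear in 3D) upsampling in the decoder; channel
width doubles per scale. Every skip connection passes through an additive
attention gate fed by the skip features `x` and a gating signal `g` = the
previous (coarser) decoder output resampled to `x`'s grid:

    α = sigmoid( ψ( ReLU( W_x·x + W_g·g + b ) ) ),   gated = α ⊙ x

`W_x`, `W_g`, ψ are 1×1(×1) convolutions; the intermediate width is half the
skip width. With `multidim_attention` (default) ψ emits one attention map
per class; since a K-map α cannot multiply a C-channel `x` elementwise for
K ≠ C, the per-class maps are averaged into a single per-voxel coefficient
before gating, which preserves the contract that the gated output has
exactly `x`'s shape. Defaults: 4 scales, 16 base channels, 3 classes, 3D;
the test scale used throughout the suite is 2 scales / 8 channels.

Patch spatial sizes must be divisible by 2^(scales−1); indivisible patches
are an explicit error rather than silently padded. Weights use Kaiming
(He) normal initialisation; the forward pass is deterministic.

**Instance normalization** is an architectural default of this package.
Without normalization, Dice-only training reliably collapses into the
all-background solution: the softmax saturates there, and the Dice
gradient — multiplicative in the predicted probability — vanishes. With
per-instance channel standardisation the same optimiser and loss converge in
a few hundred steps. Both 2D and 3D modes share this block structure.

## Autodiff engine

No deep-learning framework is used; `pclseg.nn` is a ~400-line tape-based
reverse-mode autodiff over numpy with exactly the operations the network
needs. Convolution is evaluated channels-last as one broadcast matmul per
kernel offset (3^d accumulations), which avoids the cache-hostile im2col
gather; the input gradient is the correlation with the spatially flipped,
channel-swapped kernel. Max-pool gradients split ties evenly within a
block. The factor-2 linear resampler aligns voxel centres
(source coordinate (j+0.5)/2 − 0.5, clamped at edges) and its adjoint is
closed-form even/odd slice arithmetic. The softmax + Dice loss is a single
fused node whose softmax runs in float64 so that saturated logits keep a
live gradient. Every vector–Jacobian product is tested against central
finite differences.

## Training

Loss: 1 − mean over classes of soft Dice, pooled over the batch, with
ε = 1e-5 in numerator and denominator; the background class is included in
the mean by default (configurable). Optimiser: Adam from lr 1e-4 (the
full-scale default; test-scale runs use 5e-3, appropriate for a
~20k-parameter network on high-contrast phantoms). The learning rate is
multiplied by 0.1 when the validation loss has not improved for 30 epochs
and never drops below 1e-6 — the plateau rule is one reading of a tersely
specified schedule ("decay to 1e-6 on plateau") and is fully configurable.
Full-scale defaults are 700 epochs, batch 4, 160×160 in-plane patches;
patches are 3D slabs (default depth 16) with a per-slice 2D mode available.
The validation split is a held-out fraction (default 0.1) of the training
studies; with too few studies the training loss drives the scheduler.

Cysts occupy ≲1% of a volume, so patch sampling optionally forces a
foreground voxel into the patch with probability `fg_bias` (default 0.5):
a uniform draw over the offsets whose window contains a randomly chosen
foreground voxel. All sampling is seeded; identical seeds give identical
histories.

## Inference and TTA

Whole volumes are covered by sliding 160×160(×depth) patches at stride
patch/2 (the last window along each axis is flushed to the boundary);
overlapping logits are averaged per voxel. TTA applies four invertible
in-plane transforms — rotations **+7° and −11°** about the in-plane centre
and translations of **+5 and +10 voxels** along the first in-plane axis
(the axis is a package choice; the magnitudes are fixed) — infers each
transformed copy, and maps per-class scores back with the inverse transform
using linear interpolation (never nearest-neighbour on labels). Scores from
the four transformed passes and the untransformed pass are averaged
*before* the softmax (averaging after the softmax would make the trailing
softmax a no-op, so pre-softmax scores are the coherent reading); the label
map is the per-voxel argmax. Voxels that re-enter the field of view after
the inverse transform are tracked with a validity mask and excluded from
that pass's average; intensities are padded with the window minimum.

## Postprocessing

Three filters, in order, each only ever removing voxels (the pipeline is
idempotent):

1. **Abdomen mask**: threshold the raw HU volume at −500 HU, keep the
   largest 26-connected component, fill internal holes, erode with a ball of
   radius 3 voxels. Predicted pancreas/cyst voxels outside the mask are
   cleared. Threshold and radius are unstated upstream; both are exposed in
   the config.
2. **Pancreas contact**: cyst components (26-connected; configurable) with
   no voxel adjacent — 26-neighbourhood by default, 6/18 available — to a
   *predicted* pancreas voxel are removed. Contact is evaluated against the
   prediction, not ground truth, so the pipeline runs on unlabeled studies.
3. **Minimum size**: components with fewer than **10 voxels** are removed;
   exactly 10 survives (the stated minimum is the smallest acceptable size).

Each input cyst component is reported once with the first filter that
eliminated it (`removed_by` ∈ {none, abdomen, contact, size}); straddling
components keep their inside-mask voxels. Components are identified on the
input prediction, so a component split in two by the abdomen mask is still
tracked (and size-checked) as one entity.

## Evaluation

Case studies are TP when any surviving predicted cyst component shares ≥ 1
voxel with the truth cyst mask (the weakest defensible criterion, since the
upstream definition is unstated; the overlap threshold is configurable),
else FN. Controls are FP when any predicted cyst survives, else TN.
Sensitivity = TP/(TP+FN) overall and per risk group; specificity =
TN/(TN+FP) over controls only and shared across groups. A metric with an
empty denominator is reported as absent, not as a number. Voxel-level Dice
(2|P∩T|/(|P|+|T|), 1.0 when both masks are empty) is reported per class
alongside.

## Synthetic phantoms

A phantom is a superellipse (power 4) soft-tissue cross-section with a fat
ring and air outside, a posterior vertebral cylinder of bone, an elongated
ellipsoidal pancreas slightly anterior of centre, and spherical cysts.
Tissue HU models (mean ± Gaussian sd): air −1000±20, fat −100±10, cyst 8±8,
soft tissue 40±10, pancreas 55±10, bone 300±30 — inside the standard CT
bands and ordered air < fat < cyst < soft < bone. The ~47 HU cyst–pancreas
separation makes these *high-contrast* lesions. Attached cysts are seeded
on the pancreas surface, which guarantees the contact filter's positive
path; placement retries are bounded and failure is an explicit error.
Default grid 64×64×32 voxels at 1.5×1.5×5 mm (desk-scale CPU training);
cyst radii 2–4 voxels, with high-risk cysts drawn from the upper half of the
radius band and low-risk from the lower half. Cohorts alternate case risk
groups and stratify the train/test split by case/control with
floor(ratio·n) training studies per stratum.

What the phantoms deliberately do **not** model: anatomical shape realism,
contrast phases, scanner artefacts, partial-volume effects, inter-patient
variability, or low-contrast lesions. Passing the end-to-end suite shows the
pipeline's machinery — preprocessing, optimisation, TTA merging, filtering,
scoring — works and is reproducible; it says nothing about clinical
accuracy, which requires real annotated CT data.

## Scales used in the shipped tests

Test-scale runs use a 2-scale, 8-base-channel 3D network on 32³ patches of
64×64×32 phantoms: a 200-step single-phantom overfit (expected final Dice
loss < 0.1) and a cohort run training on 20 cases + 8 controls and
evaluating a held-out 10 + 4 (expected sensitivity ≥ 0.8, specificity
≥ 0.75). These sizes are the package's chosen desk-scale study conditions;
the full-scale defaults above remain available through the configs.

## Known limitations

- The numpy engine is single-node, CPU-only; full-scale (700-epoch,
  240×240×slices) training is out of its intended range.
- The plateau learning-rate rule is one interpretation of an ambiguous
  specification; alternatives (fixed decrement, exponential decay) can be
  expressed through the config but are not implemented as modes.
- The translation-TTA axis is fixed (configurable), as the upstream
  direction is unstated.
- Per-patient aggregation of multi-study patients is not implemented;
  metrics count studies.
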