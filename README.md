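# pclseg

Automated detection of **pancreatic cystic lesions (PCLs)** in abdominal CT.
PCLs are fluid-filled pancreatic lesions — some subtypes (IPMN, MCN) are
precursors of pancreatic cancer, and many are missed as incidental findings.
`pclseg` implements a complete detection pipeline for 3D CT volumes:

1. **Preprocessing** — soft-tissue windowing (clip HU to 50 ± 100, rescale to
   [0, 1]) and central in-plane cropping (512×512 → 240×240) around the
   anatomical position of the pancreas.
2. **Segmentation** — an attention-gate U-Net ("AGNet"): a U-Net
   encoder/decoder whose skip connections pass through additive attention
   gates

   α = σ( ψ( ReLU( W_x·x + W_g·g + b ) ) ),  output = α ⊙ x

   where `x` is the skip feature map and `g` a gating signal from the coarser
   decoding stage. Trained with Adam and the multiclass soft-Dice loss
   (background / pancreas / cyst).
3. **Test-time augmentation** — four invertible in-plane transforms
   (rotations +7°/−11°, translations +5/+10 voxels); per-class scores are
   averaged over the five passes before a softmax and per-voxel argmax.
4. **Postprocessing** — three false-positive filters: an eroded abdomen mask,
   removal of cysts not in touch with the predicted pancreas, and a minimum
   component size of 10 voxels.
5. **Evaluation** — study-level sensitivity/specificity, stratified by cyst
   risk group (high = mucinous IPMN/MCN, low = serous/pseudocyst), plus
   voxel-level Dice.

Because clinical CT data cannot ship with a package, `pclseg` includes a
first-class **synthetic phantom generator**: superellipse abdomen with fat
ring and air background, vertebral bone, an elongated ellipsoidal pancreas
and near-water spherical cysts seeded on the pancreas surface, with per-tissue
Gaussian HU noise and case/control + risk-group cohort metadata. Every stage
of the pipeline is developed and tested against these phantoms.

The network runs on a small numpy reverse-mode autodiff engine built into the
package (`pclseg.nn`); no deep-learning framework is required, and every
custom gradient is verified against finite differences in the test suite.

## Worked example

```bash
python examples/03_train_tiny_network.py     # ~3 min on one CPU
python examples/04_tta_inference_and_postprocess.py
```

The first script trains a test-scale network (2 scales, 8 base channels,
32³ patches, 200 steps) on two phantoms and prints the per-epoch Dice loss:

```
epoch  0: dice loss 0.7035 (lr 5.0e-03)
epoch 10: dice loss 0.2996 (lr 5.0e-03)
epoch 19: dice loss 0.0448 (lr 5.0e-03)

parameters: 19558
checkpoint: scratch/tiny_model.npz
```

A loss of 0.045 means the mean Dice over the three classes is ~0.96 (a
network that only ever predicts background sits at 0.67). The second script
segments an unseen phantom with the full TTA merge and filters the
prediction:

```
probability channels sum to 1: max |sum-1| = 3.3e-16
raw prediction: 303 cyst voxels, 2760 pancreas voxels
  cyst component 1: 154 vox, touches pancreas=True, removed_by=none
  cyst component 2: 149 vox, touches pancreas=True, removed_by=none
after filtering: 303 cyst voxels
cyst Dice vs ground truth: 0.957
```

Surviving cyst components are the study's detections; `removed_by` names the
filter (abdomen / contact / size) that discarded a false positive.

The same stages are available as a CLI:

```bash
pclseg make-phantoms data/ --n-cases 6 --n-controls 3
pclseg train data/manifest.csv model.npz --config cfg.yaml
pclseg run data/manifest.csv model.npz out/ --config cfg.yaml
```

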