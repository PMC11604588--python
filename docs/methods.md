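# Methods

## The segmentation problem

Glioblastoma appears on multimodal MRI as three clinically meaningful
subregions: the necrotic core (NC), the contrast-enhancing tumor rim (ET),
and the surrounding peritumoral edema (ED).  The four standard sequences
carry complementary contrast — edema is bright on FLAIR and T2, the
enhancing rim is bright and the necrotic core dark on contrast-enhanced T1
(ceT1), and plain T1 has comparatively little tumor contrast.  The package
segments all three subregions plus background from a stack of co-registered
3D volumes, one channel per modality.

## Architecture

A single shared encoder feeds two decoders whose outputs are joined by a
fusion head:

* **Encoder** — VGG16 convolutional layout: five blocks of (2, 2, 3, 3, 3)
  3×3×3 convolutions (13 in total), each convolution followed by batch
  normalization and ReLU, each block followed by 2×2×2 max-pooling that
  records its argmax indices.  Channel widths start at `base_width`
  (default 8) and double per block, capped at `max_width` (default 128).
  The doubling progression is a design choice anchored at the first-block
  width; only the first width is externally fixed.
* **Skip-connection decoder** (U-Net style) — per level: trilinear 2×
  upsampling, concatenation with the encoder feature map saved at that
  resolution, then the block's convolutions.  Trilinear upsampling +
  convolution was chosen over transposed convolution to avoid checkerboard
  artifacts.
* **Pooling-index decoder** (SegNet style) — per level: max-unpooling
  driven by the recorded indices (zeros elsewhere), then convolutions; no
  skip concatenation anywhere in this path.
* **Fusion head** — the two decoders' final full-resolution feature maps
  (both `base_width` channels) are combined by elementwise addition (A),
  elementwise multiplication (M), or channel concatenation (C), and a
  single shared 1×1×1 convolution maps the fused features to class scores,
  softmax-normalized per voxel.  Fusing before one shared classifier (as
  opposed to classifying per decoder and fusing probabilities) is a design
  choice; the alternative reading of "joint output layer" was rejected to
  keep a single calibrated output.

Because both decoders consume one and the same encoder pass, the
bottleneck features of the two paths are bitwise identical — a property
the test suite asserts by recomposing `encode → decode_skip / decode_index
→ fuse → classifier` and comparing with the fused forward pass.

The network is implemented directly on numpy: each layer (3D convolution,
batch normalization, ReLU, max-pooling with indices, max-unpooling,
trilinear upsampling) carries a hand-written backward pass, and every
backward pass is validated against central finite differences in float64.
Convolutions are evaluated as one GEMM per kernel offset over shifted
views of the padded input, which keeps memory at feature-map scale.

Weight initialization is He-normal (fan-in, the natural default for ReLU
networks), biases zero, drawn from a recorded integer seed; all runs are
bitwise reproducible on CPU.

## Loss

Voxelwise multi-class cross-entropy, averaged over all voxels of the
volume: `L = −(1/(H·W·D)) Σ_voxels Σ_c y log ŷ`.  Predicted probabilities
are clamped below at 1e-12 before the log.  The loss is unweighted — class
imbalance is addressed through the data, not per-class weights.  The
training path uses the fused softmax/cross-entropy gradient
`(softmax − onehot)/N_voxels`; the test suite checks it against the
reference definition and a literal quadruple loop.

## Optimization

Plain SGD (no momentum, no weight decay — only the algorithm name is
externally fixed, so the simplest variant is used) with
`lr(epoch) = lr0 · decay^epoch`, defaults `lr0 = 0.01`, `decay = 0.8`
applied per epoch, 20 epochs, batch size 5.  The "best" checkpoint is the
one maximizing mean validation Dice over the three subregions (the
selection rule was unspecified; mean subregion Dice is the package's
choice).  Batch order in epoch *k* depends only on `seed + k`, so training
resumes deterministically from a checkpoint.

## Evaluation metrics

Per subregion, one-vs-rest, per subject:

* recall `TP/(TP+FN)`, precision `TP/(TP+FP)`,
  Dice `2TP/(2TP+FP+FN)` (harmonic mean of the former two),
  LFPR `FP/(FP+TN)`;
* AVD — mean relative volume difference `|V_pred − V_true|/V_true`, one
  volume pair per subject per class, averaged over subjects with nonzero
  true volume (matching per-class table columns);
* ASSD — average symmetric surface distance between boundary voxel sets.
  A surface voxel is a mask voxel with at least one of its 6 face
  neighbors outside the mask (volume border counts as outside); points
  are voxel centers scaled by the voxel spacing (face centers would be the
  alternative; voxel centers were chosen).  Nearest-neighbor distances use
  a k-d tree, with an all-pairs brute-force path kept as the independent
  cross-check.

Degenerate cases are reported, not silently patched: a metric with an
empty denominator is NaN and excluded from cohort aggregation (with the
exclusion counted), while an empty prediction against nonempty truth
scores 0 for recall/precision/Dice and NaN for ASSD.  Cohort aggregation
is mean ± population (divide-by-n) standard deviation — the SD convention
is a design choice.  LFPR is reported raw; its values are small because
background dominates the volume, and no rescaling is applied.

## Padding and augmentation

Native-resolution volumes (240×240×155) are zero-padded (labels:
background-padded) to the smallest power-of-two cube, 256³, content
centered with the extra voxel on the high side of odd margins
((8,8), (8,8), (50,51)); the margins are recorded so cropping recovers the
original bitwise.  Augmentation applies five pure index permutations
jointly to all channels and the labels: horizontal flip, vertical flip,
and 90/180/270° rotations, interpreted in the axial plane of the
canonical volume (the anatomical axes of the flips are not externally
fixed; the axial-plane convention is the package's choice, and the slice
axis is never flipped).  Expansion is eager — 500 originals become exactly
3 000 training samples — with a streaming iterator available.
Augmentation is applied strictly after the subject-level split, so no
transformed copy of a test subject can reach training.

## Synthetic phantoms

Each phantom is three nested ellipsoidal shells (NC ⊂ NC∪ET ⊂ NC∪ET∪ED)
around a center jittered uniformly by up to `center_jitter` voxels, with
per-subject axis ratios drawn from [0.7, 1.3] (ellipsoids rather than
spheres so that flips/rotations yield genuinely distinct samples).
Defaults: edge 64 with shell radii (20, 12, 6) voxels, scaled
proportionally for other edges (desk-scale 32³ phantoms use (10, 6, 3));
1 mm isotropic spacing; Gaussian blur σ = 1 voxel emulating diffuse
subregion borders; additive Gaussian noise σ = 0.05 on a 0–1 intensity
scale.  The intensity table fixes the qualitative modality contrasts
described above (FLAIR/T2 edema-bright, ceT1 rim-bright/core-dark, T1
low-contrast).

What the phantoms do **not** emulate: scanner physics, bias fields,
multi-focal or infiltrative tumor geometry, inter-annotator boundary
ambiguity, or registration artifacts.  Passing tests therefore demonstrate
that the architecture, loss, metrics and pipeline are implemented
correctly and that the network is trainable end to end — not that it
reaches clinical-grade accuracy on patient data.

## Problem sizes

All shipped tests and the acceptance script run on one CPU at desk scale,
a first-class configuration of every operation: 32³ inputs, base width 4,
three encoder blocks (conv layout (2, 2, 3)).  The trainability checks
are (i) overfitting one fixed phantom for up to 200 SGD steps at lr 0.01,
reaching whole-tumor Dice > 0.9 for at least one of three initialization
seeds, and (ii) a 20-subject cohort run — split 12/4/4, training split
augmented to 72 samples, 5 epochs, batch 5 — which finishes in a few
minutes with decreasing loss and a complete metric report.  The modality
sweep trains one model per nonempty subset (15 runs) and is exercised at
16³ in the tests.  Full-scale runs (256³, 500 training subjects, 20
epochs) use the same code paths but are not part of the test suite.

## Known limitations

* CPU-only numpy execution: full-resolution 256³ training is functional
  but far slower than a GPU framework; the implementation targets
  correctness and desk-scale experiments.
* Batch normalization uses batch statistics with small batches (≤5), so
  validation metrics early in training are noisy until the running
  averages settle.
* Tie-breaking in the voxel argmax prefers the lowest class index
  (background first) — deterministic, but it means exact probability ties
  favor background.
* AVD is computed per class over whole-class volumes, not per connected
  lesion component; multi-focal volume errors that cancel within a class
  are invisible to it.
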