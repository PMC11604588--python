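# fusionnet3d

Dual-decoder 3D brain-tumor segmentation at desk scale, for people who
want to study *encoder–decoder fusion architectures* — not to ship a
clinical model.  The package implements, end to end and on a single CPU:

* **the network**: one shared VGG16-style 3D encoder (13 convolutional
  layers in five blocks, channel widths 8→128) feeding two decoders — a
  skip-connection decoder that upsamples and concatenates saved encoder
  features (U-Net style), and a pooling-index decoder that max-unpools
  with the argmax indices recorded during encoding (SegNet style).  A
  fusion head joins the two full-resolution outputs by elementwise
  addition (**A**), elementwise multiplication (**M**) or channel
  concatenation (**C**) before a shared 1×1×1 voxelwise classifier;
* **the loss**: voxelwise multi-class cross-entropy
  `L = −(1/(H·W·D)) Σ_{h,w,d} Σ_c y_{hwdc} log ŷ_{hwdc}`;
* **the evaluation suite**: per-subregion recall, precision, Dice
  `2TP/(2TP+FP+FN)`, lesion false-positive rate `FP/(FP+TN)`, average
  volume difference `(1/N) Σ |V_pred − V_true|/V_true`, and average
  symmetric surface distance
  `½(mean_{p∈P} d(p,G) + mean_{g∈G} d(g,P))`, with mean ± SD cohort
  aggregation and explicit NaN conventions for empty predictions;
* **the data plumbing**: zero-padding of native 240×240×155 volumes to
  256³, the six-fold flip/rotation augmentation scheme, NIfTI I/O, and a
  synthetic multimodal glioma phantom generator (nested
  necrotic-core / enhancing-tumor / edema ellipsoids with FLAIR / T1 /
  ceT1 / T2 contrast) so nothing requires patient data;
* **orchestration**: SGD training with exponential learning-rate decay
  (`0.01 · 0.8^epoch`, 20 epochs, batch 5 by default), subject-level
  splits, modality-subset sweeps (all 15 combinations), checkpoints with
  the architecture embedded, and slice overlays (necrotic core red,
  enhancing tumor yellow, edema green).

The network itself — forward passes *and* backpropagation — is written
directly on numpy; every backward pass is verified against central finite
differences in the test suite.

## Worked example

Train the additive-fusion variant on a 20-subject phantom cohort at desk
scale (32³ volumes, base width 4, three encoder blocks) and evaluate on
the held-out test subjects:

```python
from fusionnet3d import FusionNetConfig, phantom, pipeline

cohort = phantom.generate_cohort(20, master_seed=0, edge=32)
cfg = FusionNetConfig(in_channels=4, base_width=4, num_blocks=3,
                      fusion_mode="A", input_edge=32)
tc = pipeline.TrainConfig(epochs=5, seed=0, split=(12, 4, 4))
model, history, report = pipeline.run_experiment(cohort, cfg, tc)
print(f"train loss: {history[0]['train_loss']:.3f} -> {history[-1]['train_loss']:.3f}")
frame = report.to_csv(None, method="FusionNet-A")
print(frame[["subregion", "recall", "precision", "dice", "assd"]].to_string(index=False))
```

which prints (about two minutes on one CPU):

```
train loss: 1.513 -> 0.761
subregion    recall precision      dice      assd
       NC 0.06±0.03 0.00±0.00 0.01±0.00 7.36±0.16
       ED 0.34±0.02 0.51±0.05 0.41±0.01 1.36±0.07
       ET 0.47±0.02 0.12±0.01 0.20±0.02 2.55±0.13
       WT 0.83±0.03 0.47±0.08 0.59±0.06 2.31±0.21
```

Five epochs of a tiny model on twenty synthetic subjects is a smoke run,
not a benchmark: the loss falls steadily and the whole-tumor (WT) region
is already localized (Dice 0.59, mean surface distance 2.3 mm), while the
small necrotic core — hardest subregion at full scale too — is barely
found yet.  Longer desk-scale training drives single-phantom whole-tumor
Dice above 0.9 (that check is part of the test suite).  The same code
paths scale to 256³ inputs and the full five-block architecture.

The same workflow is available from a shell:

```bash
fusionnet3d phantom --n 20 --edge 32 --out cohort/
fusionnet3d train --data cohort/ --out run/ --fusion-mode A
fusionnet3d overlay --data cohort/phantom-000_original --plane axial --index 16 --out slice.png
```

## Layout

```
src/fusionnet3d/
  nn.py            numpy layers with hand-written backward passes
  model.py         config, encoder/decoders, fusion head, checkpoints
  loss.py          voxelwise cross-entropy
  metrics.py       six-metric suite + cohort aggregation
  augmentation.py  padding + flip/rotation expansion
  phantom.py       synthetic multimodal cohort generator
  pipeline.py      splits, SGD training, sweeps, overlays
  io.py, cli.py    NIfTI I/O and the command line
docs/methods.md    model, conventions, design choices, limitations
```
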