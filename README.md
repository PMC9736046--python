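# vesselseg — collaborative-patch retinal vessel segmentation

Automatic delineation of the retinal vasculature in fundus photographs is
a standard early-screening aid for diabetic retinopathy, glaucoma and
other eye disease: morphological changes in the vessel tree often precede
symptoms.  Patch-based training is the usual way to fit a segmentation
network to the small public datasets (DRIVE, STARE) on modest hardware,
but cutting an image into patches severs every vessel that crosses a
patch border and discards the neighbourhood context that would have
disambiguated it.

`vesselseg` implements a *collaborative patch* strategy around a
two-stage segmentation network.  For each small target patch **S**
(72 × 72 by default) it also extracts five large patches
**L₁ … L₅** (144 × 144) that all contain the target region — one
centred on it and one toward each corner — so every side of the lost
neighbourhood is represented wherever the target sits in the image:

* a **pre-segmentation U-Net** produces a rough vessel probability and a
  feature map for each of the six patches;
* an **associated-information fusion** module cuts each large-patch
  feature back to the target region, mixes the five cuts through channel
  attention, and injects the result — together with a learnable
  Sobel-initialised **edge map** — into the main stage;
* the **main U-Net** carries an *adaptive coordinate attention* (ACA)
  block after each encoder stage and a *gated self-attention* (GSA) block
  at the bottleneck;
* an **associated-information correction** head repeats the cut-and-fuse
  step on the main-stage features and merges it with the small-patch
  feature to produce the final probability map.

The two attention blocks are the interesting parts.  ACA encodes each
channel by 1-D average *and* maximum pooling along rows and columns
(Kᵃ, Kᵐ per direction), passes both through a shared bottleneck
transform, and recombines them with learnable scalars g₁, g₂ before
per-direction sigmoid gates f_h, f_w rescale the feature map
(y_c(i,j) = T_c(i,j)·f_h(i)·f_w(j)); the max branch keeps one-pixel-wide
capillaries from being averaged into the background.  GSA is windowed
multi-head self-attention, Attention(Q,K,V) = softmax(QKᵀ/√d + g_a·B)V,
whose relative-position bias **B** is multiplied by a learnable scalar
gate g_a — on small datasets the bias table is the slowest part to
train, and the gate lets the network fade it out rather than suffer from
it.  Unshifted and cyclically shifted window partitions alternate.

Everything is evaluated only inside the circular field-of-view (FOV)
mask: accuracy, sensitivity, specificity, F1 from the confusion counts,
and AUC by the exact Mann–Whitney rank statistic.

The network core (reverse-mode autodiff, convolutions, instance/layer
norm, Adam) is implemented in numpy inside `vesselseg.nn`; standard imaging
steps go through scikit-image, scipy, imageio and Pillow.  A synthetic
fundus generator (branching, width-tapering vessel trees on a noisy disc
with exact ground truth) makes the whole pipeline runnable and testable
without any dataset download.

## Worked example

```bash
# build a miniature dataset: 12 training + 4 test images, 192x192
vesselseg synth --out-dir data/synth --n-train 12 --n-test 4 --size 192 --seed 0

# train a desk-scale model (reduced channel widths), then predict + score
vesselseg train --dataset data/synth --out-dir runs/demo \
    --channels 4,8,16 --epochs 30 --seed 0
vesselseg predict --dataset data/synth --checkpoint runs/demo/checkpoint.npz \
    --out-dir runs/demo/pred --stride 72
vesselseg evaluate --dataset data/synth --predictions runs/demo/pred \
    --out runs/demo/metrics.json
```

The same run through the library API:

```python
from vesselseg.network import CollabPatchNet
from vesselseg.synthetic import suite_records
from vesselseg.training import (smoke_model_config, smoke_train_config,
                                train, evaluate_records)

train_recs, test_recs = suite_records(12, 4)
model = CollabPatchNet(smoke_model_config(seed=0))
log = train(model, train_recs, smoke_train_config(seed=0, epochs=30))
print(round(log[0]["loss"], 3), "->", round(log[-1]["loss"], 3))
print({k: round(v, 4) for k, v in
       evaluate_records(model, test_recs, stride=72)["mean"].items()})
```

prints (seed 0, ~5 minutes on one CPU core):

```
3.202 -> 1.899
{'ACC': 0.9598, 'SE': 0.7983, 'SP': 0.9757, 'F1': 0.7804, 'AUC': 0.9808}
```

i.e. the training loss falls by over a third in 30 epochs and the model
recovers about 80% of vessel pixels on the held-out synthetic images at
96% overall accuracy — desk-scale numbers that demonstrate the pipeline
learns, not clinical performance.

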