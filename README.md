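# sproutnet

Detection, evaluation and line-crossing counting of crop seedlings and
look-alike weeds in overhead (UAV-style) RGB imagery — built around a
nano-scale anchor-free detector with three targeted modifications:

* **Multi-scale adaptive stage block** — the backbone's C2f bottleneck
  is replaced by a grouped block that runs a quarter of the channels
  through each of 1×1/3×3/5×5 convolutions, reweights each group with a
  softmax channel attention over pooled channel means, passes a quarter
  through untouched, and mixes with a 1×1 convolution. Lighter than the
  dense bottleneck it replaces (3.0 M → 2.7 M parameters network-wide).
* **Bidirectional weighted P2 neck** — four pyramid levels P2–P5 fused
  by one top-down and one bottom-up sweep of fast-normalised weighted
  sums, `out = Node(Σ wᵢxᵢ / (Σ wᵢ + β))` with learned nonnegative
  weights; the fine P2 level feeds small-object detail into the P3 head
  (3.0 M → 2.0 M).
* **MPDIoU box loss** — `1 − IoU + (d₁² + d₂²)/(w² + h²)`, penalising
  the squared distances between matched top-left and bottom-right
  corners, normalised by the squared image diagonal. Parameter-free.

With all three: 1.9 M parameters, a 1.1 M reduction from baseline.

The package is intended for people studying lightweight detectors for
plant phenotyping who need every component verifiable without a GPU or
a field dataset: a deterministic synthetic field generator (green lobed
seedlings, thin weed blades, film-glare occlusion, class imbalance)
stands in for UAV data, and the whole stack — including training — runs
on one CPU through an in-package numpy autodiff core.

## Worked example

```python
import numpy as np
from sproutnet import (SceneSpec, VariantConfig, assemble, gen_field_video,
                       Detection, params_table)
from sproutnet.tracking import CentroidTracker, ReferenceLine, count_video

# parameter budgets of the ablation variants
for name, row in params_table(num_classes=2).items():
    print(name, row)

# count seedlings/weeds crossing the centre line of a synthetic fly-over
spec = SceneSpec(size=160, n_seedlings=20, n_weeds=5, seed=3)
frames, tracks, expected = gen_field_video(spec, n_frames=50, sweep_speed=8.0)
dets = [[Detection(np.array(b), c, 1.0) for _, c, b in fr] for fr in tracks]
line = ReferenceLine.center_of(160, 160, "vertical")
print(count_video(None, dets, line, CentroidTracker(max_dist=30))["counts"])
```

prints

```
model0 {'params': 3011222, 'params_m': 3.0}
model1 {'params': 2707118, 'params_m': 2.7}
model2 {'params': 2045988, 'params_m': 2.0}
model3 {'params': 3011222, 'params_m': 3.0}
model4 {'params': 1884348, 'params_m': 1.9}
model5 {'params': 2707118, 'params_m': 2.7}
model6 {'params': 2045988, 'params_m': 2.0}
ms {'params': 1884348, 'params_m': 1.9}
{0: 20, 1: 5}
```

— the eight ablation variants land on the 3.0/2.7/2.0/1.9 M pattern
(the loss switch adds no parameters), and the counter recovers exactly
the 20 seedlings and 5 weeds that cross the reference line during the
simulated sweep.

The `examples/` directory holds one short script per capability: box
losses, the multi-scale block, variant parameter budgets, scene and
video synthesis, evaluation metrics, line counting, and a tiny CPU
training run. A `sproutnet` CLI wraps the pipeline
(`synth` / `train` / `eval` / `count` / `params`); training defaults to
a desk-scale profile (image 160, batch 8, 30 epochs) with the
field-scale profile (1280/32/300) available as configuration.

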