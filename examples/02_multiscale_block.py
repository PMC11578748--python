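"""The multi-scale adaptive convolution block, step by step.

Builds a small MultiScaleConv, pushes a feature map through it and shows
the per-group channel-attention weights plus the parameter saving of the
multi-scale stage block over the baseline stage block.
"""

import numpy as np

from sproutnet.blocks import (C2f, MultiScaleConv, channel_attention_weights,
                              channel_group_split)
from sproutnet.nn import Tensor, seed_all

seed_all(0)
rng = np.random.default_rng(0)

x = rng.normal(size=(16, 8, 8)).astype(np.float32)
a, b, c, d = channel_group_split(x)
print("input 16x8x8 split into four groups of", a.shape)

# attention descriptor: softmax over pooled channel means of one group
w = channel_attention_weights(a)
print("group-A attention weights (sum=1):", np.round(w, 3), "->", w.sum())

ms = MultiScaleConv(16)
out = ms(Tensor(x[None]))
print("MultiScaleConv output shape:", out.shape, "(spatial size preserved)")

for width in (32, 64, 128):
    plain = C2f(width, width, n=2, shortcut=True)
    msc2f = C2f(width, width, n=2, shortcut=True, multiscale=True)
    print(f"stage width {width:>3}: C2f {plain.num_parameters():>7} params, "
          f"multi-scale {msc2f.num_parameters():>7} "
          f"(-{1 - msc2f.num_parameters() / plain.num_parameters():.0%})")
# The grouped 1x1/3x3/5x5 branches + attention replace one dense 3x3
# convolution, which is where the backbone's parameter reduction comes from.
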