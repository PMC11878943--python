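"""The three attention gates: SE, GCA and CBAM.

Each multiplies the feature map by factors in (0, 1); with zeroed learned
weights every sigmoid gate sits at exactly 0.5.
"""

import numpy as np

from foalwatch import AttentionConfig, build_backbone
from foalwatch.nn_blocks import (CBAM, GCAAttention, SEAttention,
                                 cbam_attention, gca_attention, se_attention)

rng = np.random.default_rng(3)
x = np.abs(rng.normal(size=(16, 12, 12)))

for name, mod, fn in [
    ("SE", SEAttention(16), se_attention),
    ("GCA", GCAAttention(16), gca_attention),
    ("CBAM", CBAM(16), cbam_attention),
]:
    out = fn(x, mod)
    ratio = out / np.where(x == 0, 1, x)
    print(f"{name:>4}: output/input multiplier in "
          f"[{ratio.min():.3f}, {ratio.max():.3f}] — a (0,1) gate, shape kept")

backbone = build_backbone(layout=(1, 1, 2, 1),
                          attention=AttentionConfig("CBAM"))
print("\nCBAM placement per backbone stage (after each residual unit,"
      " stages 3-4 only):", backbone.attention_module_count())
from foalwatch.autodiff import Tensor
maps = backbone(Tensor(rng.normal(size=(1, 3, 64, 64))))
print("feature maps:", {k: tuple(v.shape[1:]) for k, v in maps.items()},
      "- strides 4/8/16/32")
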