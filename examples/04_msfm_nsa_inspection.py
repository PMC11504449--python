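"""Inspect the two bespoke operators on a synthetic image.

Shows the MSFM's per-channel branch-selection weights summing to one and
the NSA gate's range, and verifies the shape contracts.
"""

import numpy as np

from spinediff import MSFM, NSA, SynthConfig, generate_pair
from spinediff.msfm import global_pool, soft_attention
from spinediff.nn import Tensor

img, _ = generate_pair(SynthConfig(seed=4))
x = Tensor(img[None, None])

msfm = MSFM(1, np.random.default_rng(0))
msfm.norm.test_mode = True
a, b, c = msfm.branch_transform(x)
s = global_pool(a + b + c)
z = msfm.compress(s)
wa, wb, wc = soft_attention(z, msfm.logit_a, msfm.logit_b, msfm.logit_c)
print(f"MSFM branch weights (3x3, 5x5, 7x7): "
      f"{wa.data.item():.3f}, {wb.data.item():.3f}, {wc.data.item():.3f} "
      f"(sum {(wa+wb+wc).data.item():.6f})")
print(f"MSFM output shape {msfm(x).shape} == input {x.shape}")

nsa = NSA(8, np.random.default_rng(1))
feat = Tensor(np.random.default_rng(2).standard_normal((1, 8, 40, 16))
              .astype(np.float32))
t = nsa.attention_gate(nsa.fine_branch(feat), nsa.spatial_branch(feat))
v = nsa(feat)
print(f"NSA gate range ({t.data.min():.3f}, {t.data.max():.3f}) in (0,1); "
      f"output shape {v.shape} == input {feat.shape}")
# The gate is a sigmoid field: values near 1 pass detail through, values
# near 0 suppress it; the residual multiplication keeps zeros at zero.
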