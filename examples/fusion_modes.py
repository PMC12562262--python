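"""The five fusion strategies applied to one pair of pooled branch features.

The attention fusion block scores each stream against a trainable kernel
and softmax-weights every feature position; the four baselines treat all
positions equally.  Printed vectors are truncated to the first 6 entries.
"""

import numpy as np

from pcgvit import attention_fuse, baseline_fuse, init_kernel

rng = np.random.default_rng(1)
f_small, f_large = rng.normal(size=64), rng.normal(size=64)
kernel = init_kernel(64, seed_or_rng=1)

fused = attention_fuse(f_small, f_large, kernel).data
print("attention :", np.round(fused[:6], 3), " (len 64)")
for mode in ("average", "min", "max", "concat"):
    out = baseline_fuse(f_small, f_large, mode).data
    print(f"{mode:9s} :", np.round(out[:6], 3), f" (len {out.size})")

# With a zero kernel the attention weights are uniform 1/64, so attention
# fusion collapses to (f_small + f_large)/64 — the scaled average baseline.
uniform = attention_fuse(f_small, f_large, np.zeros(64)).data
avg = baseline_fuse(f_small, f_large, "average").data
print("zero-kernel fusion equals 2/64 x average:",
      np.allclose(uniform, avg * 2 / 64))
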