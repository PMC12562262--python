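"""Feature-level fusion of the two branch outputs.

Each branch's token sequence is pooled to a single 64-vector by global
average pooling over the *patch* tokens (the class token is excluded — the
fusion stage is defined on the 256×64 and 64×64 patch maps).  The
attention fusion block then scores each pooled stream against a shared
trainable kernel k ∈ R⁶⁴, turns the scores into per-feature softmax
weights, and sums the weighted streams:

    s_b = f_b ⊙ k,   w_b = softmax(s_b),   fused = w_s ⊙ f_s + w_l ⊙ f_l

Four conventional baselines (elementwise average / min / max, and
concatenation) are provided for the fusion ablation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .vit import glorot_uniform

FUSION_MODES = ("attention", "average", "min", "max", "concat")


class InvalidInputError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def gap_tokens(sequence, has_class_token: bool = True) -> Tensor:
    """Global average pooling over patch tokens -> (B, D) (or (D,) unbatched).

    With ``has_class_token`` the row-0 token of each sequence is excluded
    from the mean, matching the 256×64 / 64×64 fusion inputs.
    """
    z = Tensor.as_tensor(sequence)
    unbatched = z.ndim == 2
    if unbatched:
        z = z.reshape(1, *z.shape)
    start = 1 if has_class_token else 0
    if z.shape[1] - start < 1:
        raise InvalidInputError("sequence has no patch tokens to pool")
    pooled = z[:, start:, :].mean(axis=1)
    return pooled.reshape(pooled.shape[1]) if unbatched else pooled


def attention_fuse(f_small, f_large, kernel) -> Tensor:
    """Kernel-scored softmax fusion of two pooled feature vectors."""
    fs, fl, k = (Tensor.as_tensor(t) for t in (f_small, f_large, kernel))
    if fs.shape[-1] != fl.shape[-1] or fs.shape[-1] != k.shape[-1]:
        raise ConfigurationError("f_small, f_large and kernel must share length D")
    for t in (fs, fl, k):
        if not np.all(np.isfinite(t.data)):
            raise InvalidInputError("non-finite fusion input")
    w_small = (fs * k).softmax(axis=-1)
    w_large = (fl * k).softmax(axis=-1)
    return w_small * fs + w_large * fl


def baseline_fuse(f_small, f_large, mode: str) -> Tensor:
    """Conventional fusion: elementwise average/min/max or concatenation."""
    fs, fl = Tensor.as_tensor(f_small), Tensor.as_tensor(f_large)
    if fs.shape != fl.shape:
        raise ConfigurationError("fusion inputs must have equal shapes")
    if mode == "average":
        return (fs + fl) * 0.5
    if mode == "min":
        mask = fs.data <= fl.data
        return fs * mask + fl * (~mask)
    if mode == "max":
        mask = fs.data >= fl.data
        return fs * mask + fl * (~mask)
    if mode == "concat":
        return concat([fs, fl], axis=-1)
    raise ConfigurationError(f"unknown fusion mode {mode!r}; expected one of {FUSION_MODES}")


def fuse(f_small, f_large, mode: str, kernel=None) -> Tensor:
    if mode == "attention":
        if kernel is None:
            raise ConfigurationError("attention fusion requires a kernel")
        return attention_fuse(f_small, f_large, kernel)
    return baseline_fuse(f_small, f_large, mode)


def fused_dim(embed_dim: int, mode: str) -> int:
    """Width of the fused vector fed to the classifier head."""
    if mode not in FUSION_MODES:
        raise ConfigurationError(f"unknown fusion mode {mode!r}")
    return 2 * embed_dim if mode == "concat" else embed_dim


def init_kernel(D: int, seed_or_rng, dtype=np.float32) -> Tensor:
    """Glorot-uniform trainable fusion kernel of length D.

    Treated as a D→1 linear map for fan purposes, so values lie within
    ±sqrt(6/(D+1)).
    """
    if D <= 0:
        raise ConfigurationError("D must be positive")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return Tensor(glorot_uniform(rng, (D,), fan_in=D, fan_out=1, dtype=dtype),
                  requires_grad=True)
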