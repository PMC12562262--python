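"""Vision-transformer branch: patch embedding, self-attention, encoder.

Each branch turns the 64×64×3 feature image into a token sequence —
flattened P×P×3 patches linearly projected to D=64 dimensions, a learnable
class token prepended, learnable positional embeddings added — and passes
it through L=5 pre-LN transformer encoder blocks:

    Z'_l = MSA(LN(Z_{l-1})) + Z_{l-1}
    Z_l  = MLP(LN(Z'_l))   + Z'_l

The small branch uses P=4 (256 patches, 257×64 tokens), the large branch
P=8 (64 patches, 65×64 tokens).  Attention is standard scaled dot-product
softmax(QKᵀ/√d_k)V split over h heads and re-projected by U_msa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, layer_norm, linear


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class BranchConfig:
    """Hyperparameters of one transformer branch."""

    patch_size: int
    image_size: int = 64
    channels: int = 3
    embed_dim: int = 64
    depth: int = 5
    heads: int = 4
    mlp_hidden: int = 256
    ln_eps: float = 1e-6

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ConfigurationError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}")
        if self.embed_dim % self.heads != 0:
            raise ConfigurationError(
                f"embed_dim {self.embed_dim} not divisible by heads {self.heads}")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid * self.grid

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * self.channels

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @property
    def seq_len(self) -> int:
        return self.n_patches + 1


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int | None = None, fan_out: int | None = None,
                   dtype=np.float32) -> np.ndarray:
    """Glorot/Xavier uniform draw: U(±sqrt(6/(fan_in+fan_out)))."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) >= 1 else 1
    if fan_out is None:
        fan_out = shape[-1] if len(shape) >= 2 else shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def patchify(image: np.ndarray, patch_size: int) -> np.ndarray:
    """Split an image (or batch) into flattened non-overlapping patches.

    Row order is left-to-right then top-to-bottom; each row of the output
    is one flattened P×P×C patch, so the result is Np×(P²·C) per image.
    """
    img = np.asarray(image)
    batched = img.ndim == 4
    if not batched:
        img = img[None]
    B, H, W, C = img.shape
    P = patch_size
    if H % P or W % P:
        raise ConfigurationError(f"image {H}×{W} not divisible by patch size {P}")
    gh, gw = H // P, W // P
    patches = (img.reshape(B, gh, P, gw, P, C)
                  .transpose(0, 1, 3, 2, 4, 5)
                  .reshape(B, gh * gw, P * P * C))
    return patches if batched else patches[0]


def unpatchify(patches: np.ndarray, patch_size: int, image_size: int = 64,
               channels: int = 3) -> np.ndarray:
    """Inverse of :func:`patchify` (roundtrip identity)."""
    pat = np.asarray(patches)
    batched = pat.ndim == 3
    if not batched:
        pat = pat[None]
    B = pat.shape[0]
    P = patch_size
    g = image_size // P
    img = (pat.reshape(B, g, g, P, P, channels)
              .transpose(0, 1, 3, 2, 4, 5)
              .reshape(B, image_size, image_size, channels))
    return img if batched else img[0]


def embed_sequence(patches, E, class_token, pos_embed) -> Tensor:
    """Project patches, prepend the class token, add positional embeddings.

    ``patches`` is (B, Np, P²C) (or unbatched), ``E`` is (P²C, D), the class
    token is (1, 1, D), and ``pos_embed`` is (Np+1, D).  The output is the
    (B, Np+1, D) token sequence Z0 with the class token at row 0.
    """
    p = Tensor.as_tensor(patches)
    if p.ndim == 2:
        p = p.reshape(1, *p.shape)
    E = Tensor.as_tensor(E)
    class_token = Tensor.as_tensor(class_token)
    pos_embed = Tensor.as_tensor(pos_embed)
    B = p.shape[0]
    if E.shape[0] != p.shape[2]:
        raise ConfigurationError(f"embedding matrix rows {E.shape[0]} != patch dim {p.shape[2]}")
    if pos_embed.shape[0] != p.shape[1] + 1:
        raise ConfigurationError("positional embedding length must be Np+1")
    tok = p @ E
    cls = class_token.broadcast_to((B, 1, E.shape[1]))
    z = concat([cls, tok], axis=1)
    return z + pos_embed


def scaled_dot_attention(Q, K, V) -> Tensor:
    """softmax(QKᵀ/√d_k)·V.  Works on (..., m, d) stacks."""
    Q, K, V = (Tensor.as_tensor(t) for t in (Q, K, V))
    dq, dk = Q.shape[-1], K.shape[-1]
    if dq != dk:
        raise ConfigurationError(f"query dim {dq} != key dim {dk}")
    # scale folded into Q (a small tensor) rather than the m×m score matrix;
    # the python-float scale keeps the float32 graph from promoting to float64
    scores = (Q * float(1.0 / np.sqrt(dk))) @ K.swapaxes(-1, -2)
    return scores.softmax(axis=-1) @ V


def split_heads(x: Tensor, heads: int) -> Tensor:
    """(..., N, D) -> (..., heads, N, D/heads)."""
    *lead, N, D = x.shape
    return x.reshape(*lead, N, heads, D // heads).swapaxes(-2, -3)


def merge_heads(x: Tensor) -> Tensor:
    *lead, h, N, ds = x.shape
    return x.swapaxes(-2, -3).reshape(*lead, N, h * ds)


def msa(Z, params: dict, heads: int) -> Tensor:
    """Multi-head self-attention with output projection U_msa.

    ``params`` holds ``Wq, bq, Wk, bk, Wv, bv`` (each D×D projections with
    bias) and ``Umsa, b_msa``; head outputs are concatenated then projected.
    """
    Z = Tensor.as_tensor(Z)
    if Z.ndim == 2:
        Z = Z.reshape(1, *Z.shape)
    D = Z.shape[-1]
    if D % heads:
        raise ConfigurationError(f"embed dim {D} not divisible by heads {heads}")
    q = split_heads(linear(Z, params["Wq"], params["bq"]), heads)
    k = split_heads(linear(Z, params["Wk"], params["bk"]), heads)
    v = split_heads(linear(Z, params["Wv"], params["bv"]), heads)
    out = merge_heads(scaled_dot_attention(q, k, v))
    return linear(out, params["Umsa"], params["b_msa"])


def encoder_block(Z, params: dict, heads: int, ln_eps: float = 1e-6) -> Tensor:
    """One pre-LN transformer encoder block (MSA + 2-layer GELU MLP)."""
    Z = Tensor.as_tensor(Z)
    attn = msa(layer_norm(Z, params["ln1_g"], params["ln1_b"], ln_eps), params, heads)
    Zp = attn + Z
    h = layer_norm(Zp, params["ln2_g"], params["ln2_b"], ln_eps)
    h = linear(h, params["W1"], params["b1"]).gelu()
    h = linear(h, params["W2"], params["b2"])
    return h + Zp


class ViTBranch:
    """One complete branch: patch embedding + L stacked encoder blocks."""

    def __init__(self, cfg: BranchConfig, rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        D, pd = cfg.embed_dim, cfg.patch_dim
        H = cfg.mlp_hidden

        def par(arr):
            return Tensor(arr, requires_grad=True)

        self.embed = {
            "E": par(glorot_uniform(rng, (pd, D), dtype=dtype)),
            "b_embed": par(np.zeros((D,), dtype=dtype)),
            "class_token": par(glorot_uniform(rng, (1, 1, D), fan_in=1, fan_out=D, dtype=dtype)),
            "pos_embed": par(glorot_uniform(rng, (cfg.seq_len, D), fan_in=1, fan_out=D, dtype=dtype)),
        }
        self.blocks: list[dict] = []
        for _ in range(cfg.depth):
            self.blocks.append({
                "ln1_g": par(np.ones((D,), dtype=dtype)),
                "ln1_b": par(np.zeros((D,), dtype=dtype)),
                "Wq": par(glorot_uniform(rng, (D, D), dtype=dtype)),
                "bq": par(np.zeros((D,), dtype=dtype)),
                "Wk": par(glorot_uniform(rng, (D, D), dtype=dtype)),
                "bk": par(np.zeros((D,), dtype=dtype)),
                "Wv": par(glorot_uniform(rng, (D, D), dtype=dtype)),
                "bv": par(np.zeros((D,), dtype=dtype)),
                "Umsa": par(glorot_uniform(rng, (D, D), dtype=dtype)),
                "b_msa": par(np.zeros((D,), dtype=dtype)),
                "ln2_g": par(np.ones((D,), dtype=dtype)),
                "ln2_b": par(np.zeros((D,), dtype=dtype)),
                "W1": par(glorot_uniform(rng, (D, H), dtype=dtype)),
                "b1": par(np.zeros((H,), dtype=dtype)),
                "W2": par(glorot_uniform(rng, (H, D), dtype=dtype)),
                "b2": par(np.zeros((D,), dtype=dtype)),
            })

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self.embed.items()}
        for i, blk in enumerate(self.blocks):
            out.update({f"{prefix}block{i}.{k}": v for k, v in blk.items()})
        return out

    def tokenize(self, images: np.ndarray) -> Tensor:
        """Images (B,H,W,C) -> embedded token sequence Z0 (B, Np+1, D)."""
        patches = patchify(images, self.cfg.patch_size)
        if patches.ndim == 2:
            patches = patches[None]
        z = embed_sequence(patches, self.embed["E"], self.embed["class_token"],
                           self.embed["pos_embed"])
        return z + self.embed["b_embed"]

    def encode(self, tokens) -> Tensor:
        """Apply the L encoder blocks; the full sequence is returned."""
        z = Tensor.as_tensor(tokens)
        for blk in self.blocks:
            z = encoder_block(z, blk, self.cfg.heads, self.cfg.ln_eps)
        return z

    def forward(self, images: np.ndarray) -> Tensor:
        return self.encode(self.tokenize(images))
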