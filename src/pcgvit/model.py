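"""The assembled two-stream classifier.

The model is the quadruple (B_s, B_l, A, K): a small-patch ViT branch
(P=4), a large-patch ViT branch (P=8), the fusion block A, and a
classifier head K of three fully connected layers — two 64-unit ReLU
layers and a softmax output sized to the number of classes.  Both branches
consume the *same* 64×64×3 feature image; their pooled outputs are fused
and classified.

``count_parameters`` counts trainable scalars at run time and
``parameter_count_formula`` recomputes the same number in closed form from
the configuration; the default model comes in under the 0.86 M budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, linear, no_grad
from .fusion import FUSION_MODES, fuse, fused_dim, gap_tokens, init_kernel
from .vit import BranchConfig, ConfigurationError, ViTBranch, glorot_uniform


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters for both branches, fusion and head."""

    branch_small: BranchConfig = field(default_factory=lambda: BranchConfig(patch_size=4))
    branch_large: BranchConfig = field(default_factory=lambda: BranchConfig(patch_size=8))
    fusion_mode: str = "attention"
    n_classes: int = 2
    classifier_hidden: tuple[int, int] = (64, 64)
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.fusion_mode not in FUSION_MODES:
            raise ConfigurationError(f"fusion_mode: unknown mode {self.fusion_mode!r}")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes: must be at least 2")
        if self.branch_small.embed_dim != self.branch_large.embed_dim:
            raise ConfigurationError("embed_dim: branches must share the embedding dimension")
        if len(self.classifier_hidden) != 2:
            raise ConfigurationError("classifier_hidden: head has exactly two hidden layers")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {
            "branch_small": asdict(self.branch_small),
            "branch_large": asdict(self.branch_large),
            "fusion_mode": self.fusion_mode,
            "n_classes": self.n_classes,
            "classifier_hidden": list(self.classifier_hidden),
            "seed": self.seed,
            "dtype": self.dtype,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        return ModelConfig(
            branch_small=BranchConfig(**d["branch_small"]),
            branch_large=BranchConfig(**d["branch_large"]),
            fusion_mode=d["fusion_mode"],
            n_classes=d["n_classes"],
            classifier_hidden=tuple(d["classifier_hidden"]),
            seed=d.get("seed", 0),
            dtype=d.get("dtype", "float32"),
        )


@dataclass(frozen=True)
class Prediction:
    record_id: str
    probabilities: np.ndarray
    predicted_label: int


class TwoStreamViT:
    """Two-branch vision transformer with trainable feature fusion."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(cfg.seed)
        self.branch_small = ViTBranch(cfg.branch_small, rng, dtype=dtype)
        self.branch_large = ViTBranch(cfg.branch_large, rng, dtype=dtype)
        D = cfg.branch_small.embed_dim
        self.kernel = (init_kernel(D, rng, dtype=dtype)
                       if cfg.fusion_mode == "attention" else None)
        in_dim = fused_dim(D, cfg.fusion_mode)
        h1, h2 = cfg.classifier_hidden
        self.head = {
            "Wh1": Tensor(glorot_uniform(rng, (in_dim, h1), dtype=dtype), requires_grad=True),
            "bh1": Tensor(np.zeros((h1,), dtype=dtype), requires_grad=True),
            "Wh2": Tensor(glorot_uniform(rng, (h1, h2), dtype=dtype), requires_grad=True),
            "bh2": Tensor(np.zeros((h2,), dtype=dtype), requires_grad=True),
            "Wout": Tensor(glorot_uniform(rng, (h2, cfg.n_classes), dtype=dtype), requires_grad=True),
            "bout": Tensor(np.zeros((cfg.n_classes,), dtype=dtype), requires_grad=True),
        }

    # -- parameters -----------------------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        out = self.branch_small.parameters("small.")
        out.update(self.branch_large.parameters("large."))
        if self.kernel is not None:
            out["fusion.kernel"] = self.kernel
        out.update({f"head.{k}": v for k, v in self.head.items()})
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            missing = set(params) ^ set(state)
            raise ConfigurationError(f"checkpoint/model parameter mismatch: {sorted(missing)}")
        for k, v in state.items():
            v = np.asarray(v)
            if v.shape != params[k].data.shape:
                raise ConfigurationError(f"shape mismatch for {k}: {v.shape} vs {params[k].data.shape}")
            params[k].data = v.astype(params[k].data.dtype)

    # -- forward --------------------------------------------------------------

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        cfg = self.cfg.branch_small
        expected = (cfg.image_size, cfg.image_size, cfg.channels)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != expected:
            raise InvalidInputError(f"expected images of shape {expected}, got {x.shape}")
        return x.astype(np.dtype(self.cfg.dtype))

    def forward(self, images: np.ndarray) -> Tensor:
        """Batch of feature images -> class logits (B, n_classes)."""
        x = self._check_images(images)
        f_small = gap_tokens(self.branch_small.forward(x))
        f_large = gap_tokens(self.branch_large.forward(x))
        fused = fuse(f_small, f_large, self.cfg.fusion_mode, self.kernel)
        h = linear(fused, self.head["Wh1"], self.head["bh1"]).relu()
        h = linear(h, self.head["Wh2"], self.head["bh2"]).relu()
        return linear(h, self.head["Wout"], self.head["bout"])

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Softmax class probabilities, computed without building a graph."""
        x = self._check_images(images)
        out = []
        with no_grad():
            for i in range(0, x.shape[0], batch_size):
                out.append(self.forward(x[i:i + batch_size]).softmax(axis=-1).data)
        return np.concatenate(out, axis=0)

    def predict_tiled(self, tiles: np.ndarray) -> Prediction:
        """Majority vote over the 64-frame tiles of one long recording.

        Ties are broken by the mean class probability across tiles.
        """
        probs = self.predict_proba(tiles)
        votes = np.bincount(probs.argmax(axis=1), minlength=self.cfg.n_classes)
        mean_p = probs.mean(axis=0)
        winners = np.flatnonzero(votes == votes.max())
        label = int(winners[np.argmax(mean_p[winners])])
        return Prediction("tiled", mean_p, label)

    def predict(self, images: np.ndarray, record_ids=None) -> list[Prediction]:
        probs = self.predict_proba(images)
        if record_ids is None:
            record_ids = [str(i) for i in range(probs.shape[0])]
        return [Prediction(rid, p, int(np.argmax(p))) for rid, p in zip(record_ids, probs)]


def build_model(cfg: ModelConfig | None = None) -> TwoStreamViT:
    return TwoStreamViT(cfg or ModelConfig())


def count_parameters(model: TwoStreamViT) -> int:
    """Number of trainable scalars actually registered on the model."""
    return int(sum(p.data.size for p in model.parameters().values()))


def _branch_parameter_count(b: BranchConfig) -> int:
    D, H = b.embed_dim, b.mlp_hidden
    embed = b.patch_dim * D + D          # E + embedding bias
    tokens = D + b.seq_len * D           # class token + positional embeddings
    per_block = (
        2 * D                            # LN1
        + 3 * (D * D + D)                # Wq/Wk/Wv with biases
        + D * D + D                      # Umsa with bias
        + 2 * D                          # LN2
        + D * H + H                      # MLP layer 1
        + H * D + D                      # MLP layer 2
    )
    return embed + tokens + b.depth * per_block


def parameter_count_formula(cfg: ModelConfig) -> int:
    """Closed-form trainable-parameter count from the configuration alone.

    Must agree exactly with :func:`count_parameters` on the built model;
    note the total is independent of the number of heads (head splitting
    reshapes, it does not add, projection weights).
    """
    total = _branch_parameter_count(cfg.branch_small)
    total += _branch_parameter_count(cfg.branch_large)
    D = cfg.branch_small.embed_dim
    if cfg.fusion_mode == "attention":
        total += D
    in_dim = fused_dim(D, cfg.fusion_mode)
    h1, h2 = cfg.classifier_hidden
    total += in_dim * h1 + h1 + h1 * h2 + h2 + h2 * cfg.n_classes + cfg.n_classes
    return total


# -- checkpointing -------------------------------------------------------------

def save_checkpoint(model: TwoStreamViT, path) -> None:
    """Weights as NPZ plus a JSON sidecar recording the configuration."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(model.cfg.to_dict(), indent=2))


def load_checkpoint(path) -> TwoStreamViT:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = ModelConfig.from_dict(json.loads(sidecar.read_text()))
    model = TwoStreamViT(cfg)
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model
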