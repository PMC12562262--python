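"""Training protocol and evaluation metrics.

The evaluation protocol is subject-wise throughout: 10% of *subjects* are
held out as a fixed test set, and 10-fold cross-validation is run over the
remaining 90%, so no patient ever contributes recordings to more than one
subset of a fold.  Models are trained with Adam (lr 0.008, batch 32) for
up to 400 epochs with patience-15 early stopping on validation accuracy;
the best-epoch weights are restored.

Metrics follow the standard confusion-count definitions — sensitivity
TP/(TP+FN), specificity TN/(TN+FP), F1 = 2TP/(2TP+FP+FN), accuracy, and
Score = (sensitivity+specificity)/2 — with macro one-vs-rest reductions in
the three-class case plus a class-weighted accuracy (murmur-challenge
weights present:5, unknown:3, absent:1 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor, no_grad
from .features import FeatureConfig, HeartSoundRecord, make_feature_image, standardize_images
from .model import ModelConfig, TwoStreamViT, build_model


class ConfigurationError(ValueError):
    pass


class InvalidInputError(ValueError):
    pass


MURMUR_WEIGHTS = {"present": 5.0, "unknown": 3.0, "absent": 1.0}


# -- subject-wise splitting ----------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Held-out test subjects plus (train, val) subject sets per fold."""

    test_subjects: frozenset
    folds: tuple  # of (frozenset train, frozenset val)

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_splits(records: list[HeartSoundRecord], test_frac: float = 0.1,
                n_folds: int = 10, seed: int = 0) -> SplitPlan:
    """Partition *subjects* into a test set and ``n_folds`` CV folds.

    Deterministic under ``seed``; requires at least ``n_folds + 1``
    distinct subjects so every fold has a non-empty validation set.
    """
    subjects = sorted({r.subject_id for r in records})
    if len(subjects) < n_folds + 1:
        raise ConfigurationError(
            f"need at least {n_folds + 1} subjects for {n_folds}-fold CV, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(subjects))
    n_test = max(1, round(test_frac * len(subjects)))
    test = frozenset(order[:n_test])
    rest = order[n_test:]
    if len(rest) < n_folds:
        raise ConfigurationError("not enough non-test subjects to fill the folds")
    groups: list[list] = [rest[i::n_folds] for i in range(n_folds)]
    folds = []
    for i in range(n_folds):
        val = frozenset(groups[i])
        train = frozenset(s for j, g in enumerate(groups) if j != i for s in g)
        folds.append((train, val))
    return SplitPlan(test_subjects=test, folds=tuple(folds))


def records_for(records: list[HeartSoundRecord], subjects) -> list[HeartSoundRecord]:
    subjects = set(subjects)
    return [r for r in records if r.subject_id in subjects]


# -- training ------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol (Adam, no LR scheduling, early stopping)."""

    lr: float = 0.008
    batch_size: int = 32
    max_epochs: int = 400
    patience: int = 15
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    class_weighting: bool = False
    verbose: bool = False

    def __post_init__(self):
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 0.008,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def cross_entropy(logits: Tensor, onehot: np.ndarray, sample_weight=None) -> Tensor:
    """Mean (weighted) cross-entropy from logits via log-softmax."""
    logp = logits.log_softmax(axis=-1)
    nll = -(logp * onehot).sum(axis=-1)
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=logits.data.dtype)
        return (nll * (w / w.sum())).sum()
    return nll.mean()


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes), dtype=np.float32)
    out[np.arange(len(labels)), labels] = 1.0
    return out


def evaluate_accuracy(model: TwoStreamViT, X: np.ndarray, y: np.ndarray,
                      class_weights: np.ndarray | None = None) -> float:
    """Plain (or class-weighted, 3-class mode) accuracy of argmax predictions."""
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    if class_weights is None:
        return float(np.mean(pred == y))
    w = class_weights[y]
    return float(np.sum(w * (pred == y)) / np.sum(w))


def train(model: TwoStreamViT, train_set: tuple[np.ndarray, np.ndarray],
          val_set: tuple[np.ndarray, np.ndarray], cfg: TrainConfig,
          monitor_weights: np.ndarray | None = None) -> dict:
    """Fit the model with Adam + early stopping; restore best-epoch weights.

    ``train_set``/``val_set`` are (images, integer labels).  Validation
    accuracy (optionally class-weighted via ``monitor_weights``) is the
    monitored quantity; training stops after ``cfg.patience`` epochs
    without improvement and the weights from the best epoch are restored.
    Returns a history dict with per-epoch train loss/accuracy and
    validation accuracy, plus the best epoch index.
    """
    Xtr, ytr = train_set
    Xval, yval = val_set
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ConfigurationError("train and validation sets must be non-empty")
    n_classes = model.cfg.n_classes
    Ytr = one_hot(ytr, n_classes)
    sample_w = None
    if cfg.class_weighting:
        freq = np.bincount(ytr, minlength=n_classes).astype(float)
        inv = np.where(freq > 0, 1.0 / np.maximum(freq, 1), 0.0)
        sample_w = inv[ytr]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps)
    history = {"train_loss": [], "train_acc": [], "val_acc": []}
    best_val, best_epoch, best_state = -np.inf, -1, model.state_dict()
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        losses, hits, seen = [], 0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            try:
                logits = model.forward(Xtr[idx])
                loss = cross_entropy(logits, Ytr[idx],
                                     None if sample_w is None else sample_w[idx])
            except ValueError as err:  # non-finite activations mid-forward
                raise RuntimeError(
                    f"training diverged (non-finite loss path) at epoch {epoch}: {err}") from err
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {i // cfg.batch_size}; "
                    "check learning rate and input scaling")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            hits += int((logits.data.argmax(axis=1) == ytr[idx]).sum())
            seen += len(idx)
        val_acc = evaluate_accuracy(model, Xval, yval, monitor_weights)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / seen)
        history["val_acc"].append(val_acc)
        if cfg.verbose:
            print(f"epoch {epoch:3d}  loss {history['train_loss'][-1]:.4f}  "
                  f"train_acc {history['train_acc'][-1]:.3f}  val_acc {val_acc:.3f}")
        if val_acc > best_val:
            best_val, best_epoch, best_state = val_acc, epoch, model.state_dict()
        elif epoch - best_epoch >= cfg.patience:
            break
    model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_acc"] = best_val
    return history


# -- metrics -------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived metric suite (fractions in [0, 1])."""

    confusion: np.ndarray
    labels: tuple
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    score: float
    weighted_accuracy: float | None = None

    def as_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
             "specificity": self.specificity, "f1": self.f1, "score": self.score}
        if self.weighted_accuracy is not None:
            d["weighted_accuracy"] = self.weighted_accuracy
        return d


def confusion_matrix(truth, pred, labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(truth, pred):
        cm[index[t], index[p]] += 1
    return cm


def _binary_counts(cm: np.ndarray, pos: int) -> tuple[int, int, int, int]:
    tp = cm[pos, pos]
    fn = cm[pos].sum() - tp
    fp = cm[:, pos].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return int(tp), int(tn), int(fp), int(fn)


def compute_metrics(truth, pred, labels=None, positive_class=None,
                    class_weights: dict | None = None) -> MetricsReport:
    """Confusion-count metrics; macro one-vs-rest reduction beyond 2 classes.

    Binary: TP/TN/FP/FN are taken against ``positive_class`` (defaults to
    the last label).  Multi-class: sensitivity/specificity/F1 are one-vs-
    rest per class and macro-averaged, classes absent from the truth are
    excluded with a warning, and a class-weighted accuracy is reported.
    """
    truth = list(truth)
    pred = list(pred)
    if len(truth) == 0 or len(truth) != len(pred):
        raise InvalidInputError("truth and pred must be equal-length and non-empty")
    if labels is None:
        labels = sorted(set(truth) | set(pred))
    cm = confusion_matrix(truth, pred, labels)
    accuracy = float(np.trace(cm) / cm.sum())
    if len(labels) == 2:
        pos = labels.index(positive_class) if positive_class is not None else 1
        tp, tn, fp, fn = _binary_counts(cm, pos)
        sens = tp / (tp + fn) if tp + fn else float("nan")
        spec = tn / (tn + fp) if tn + fp else float("nan")
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
        wacc = None
    else:
        sens_list, spec_list, f1_list = [], [], []
        for i, lab in enumerate(labels):
            tp, tn, fp, fn = _binary_counts(cm, i)
            if tp + fn == 0:
                warnings.warn(f"class {lab!r} absent from truth; excluded from macro metrics")
                continue
            sens_list.append(tp / (tp + fn))
            spec_list.append(tn / (tn + fp) if tn + fp else np.nan)
            f1_list.append(2 * tp / (2 * tp + fp + fn))
        sens = float(np.mean(sens_list))
        spec = float(np.mean(spec_list))
        f1 = float(np.mean(f1_list))
        weights = class_weights or MURMUR_WEIGHTS
        w = np.array([weights.get(lab, 1.0) for lab in labels], dtype=float)
        wacc = weighted_accuracy(cm, w)
    score = (sens + spec) / 2
    return MetricsReport(confusion=cm, labels=tuple(labels), accuracy=accuracy,
                         sensitivity=sens, specificity=spec, f1=f1, score=score,
                         weighted_accuracy=wacc)


def weighted_accuracy(confusion: np.ndarray, weights) -> float:
    """Σ_c w_c·correct_c / Σ_c w_c·total_c (rows of ``confusion`` = truth).

    Reduces to plain accuracy when all weights are equal.
    """
    cm = np.asarray(confusion, dtype=float)
    w = np.asarray(weights, dtype=float)
    if cm.sum() == 0:
        raise InvalidInputError("confusion matrix is all zeros")
    if w.shape[0] != cm.shape[0]:
        raise ConfigurationError("one weight per truth class is required")
    return float((w * np.diag(cm)).sum() / (w * cm.sum(axis=1)).sum())


# -- experiment harness --------------------------------------------------------

def prepare_features(records: list[HeartSoundRecord],
                     feature_cfg: FeatureConfig | None = None) -> tuple[np.ndarray, np.ndarray, list, np.ndarray]:
    """Extract images and integer labels for a record list.

    Returns (images, y, label_names, subject_ids); label indices follow the
    sorted label vocabulary.
    """
    feature_cfg = feature_cfg or FeatureConfig()
    labels = sorted({r.label for r in records})
    images = np.stack([make_feature_image(r, feature_cfg) for r in records])
    y = np.array([labels.index(r.label) for r in records])
    subjects = np.array([r.subject_id for r in records])
    return images, y, labels, subjects


def run_experiment(records: list[HeartSoundRecord],
                   model_cfg: ModelConfig | None = None,
                   train_cfg: TrainConfig | None = None,
                   feature_cfg: FeatureConfig | None = None,
                   fusion_modes: tuple[str, ...] = ("attention",),
                   n_folds: int = 10, test_frac: float = 0.1,
                   split_seed: int = 0, standardize: bool = True,
                   positive_class: str | None = None) -> pd.DataFrame:
    """Subject-wise CV over one or more fusion modes, evaluated on the test set.

    For every fusion mode and fold, a fresh model is trained on the fold's
    training subjects, early-stopped on its validation subjects, and
    evaluated on the common held-out test subjects.  Per-channel
    standardization statistics are fitted on each fold's training images.
    Returns one row per (fusion_mode, fold) with the full metric suite.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    images, y, label_names, subjects = prepare_features(records, feature_cfg)
    if len(label_names) != model_cfg.n_classes:
        raise ConfigurationError(
            f"records carry {len(label_names)} labels but model expects {model_cfg.n_classes}")
    if positive_class is None and model_cfg.n_classes == 2:
        positive_class = next((lab for lab in ("abnormal", "present") if lab in label_names),
                              label_names[-1])
    plan = make_splits(records, test_frac=test_frac, n_folds=n_folds, seed=split_seed)
    test_mask = np.isin(subjects, list(plan.test_subjects))
    monitor_w = None
    if model_cfg.n_classes > 2:
        monitor_w = np.array([MURMUR_WEIGHTS.get(lab, 1.0) for lab in label_names])
    rows = []
    for mode in fusion_modes:
        from dataclasses import replace
        cfg_mode = replace(model_cfg, fusion_mode=mode)
        for fold_i, (train_subj, val_subj) in enumerate(plan.folds):
            tr = np.isin(subjects, list(train_subj))
            va = np.isin(subjects, list(val_subj))
            Xtr, stats = (standardize_images(images[tr]) if standardize
                          else (images[tr], None))
            Xva = standardize_images(images[va], stats)[0] if standardize else images[va]
            Xte = standardize_images(images[test_mask], stats)[0] if standardize else images[test_mask]
            model = build_model(cfg_mode)
            history = train(model, (Xtr, y[tr]), (Xva, y[va]), train_cfg,
                            monitor_weights=monitor_w)
            pred = model.predict_proba(Xte).argmax(axis=1)
            report = compute_metrics([label_names[i] for i in y[test_mask]],
                                     [label_names[i] for i in pred],
                                     labels=label_names, positive_class=positive_class)
            row = {"fusion_mode": mode, "fold": fold_i,
                   "best_epoch": history["best_epoch"],
                   "best_val_acc": history["best_val_acc"],
                   "epochs_run": len(history["val_acc"]), **report.as_dict()}
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of each metric per fusion mode."""
    metric_cols = [c for c in results.columns
                   if c not in ("fusion_mode", "fold", "best_epoch", "epochs_run")]
    return results.groupby("fusion_mode")[metric_cols].agg(["mean", "std"])
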