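"""Subject-wise splitting, the training loop, and the metric suite."""

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion

from pcgvit.features import HeartSoundRecord
from pcgvit.model import TwoStreamViT
from pcgvit.training import (Adam, ConfigurationError, InvalidInputError, TrainConfig,
                             compute_metrics, cross_entropy, evaluate_accuracy,
                             make_splits, one_hot, train, weighted_accuracy)
from pcgvit.autodiff import Tensor


def _records(n_subjects, per_subject=2):
    out = []
    for s in range(n_subjects):
        for r in range(per_subject):
            out.append(HeartSoundRecord(record_id=f"s{s}_r{r}", subject_id=f"s{s}",
                                        samples=np.ones(100), rate=2000,
                                        label="normal"))
    return out


class TestSplits:
    def test_eleven_subjects_exact_division(self):
        plan = make_splits(_records(11), test_frac=0.1, n_folds=10, seed=0)
        assert len(plan.test_subjects) == 1
        assert plan.n_folds == 10
        assert all(len(val) == 1 for _, val in plan.folds)

    def test_subject_disjointness_exhaustive(self):
        recs = _records(23)
        for seed in range(10):
            plan = make_splits(recs, test_frac=0.1, n_folds=10, seed=seed)
            for train_s, val_s in plan.folds:
                assert not (train_s & val_s)
                assert not (train_s & plan.test_subjects)
                assert not (val_s & plan.test_subjects)
            covered = set().union(*(val for _, val in plan.folds))
            assert covered == {r.subject_id for r in recs} - plan.test_subjects

    def test_deterministic_under_seed(self):
        recs = _records(15)
        assert make_splits(recs, seed=4) == make_splits(recs, seed=4)
        assert make_splits(recs, seed=4) != make_splits(recs, seed=5)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            make_splits(_records(10), n_folds=10)


class TestMetrics:
    def test_hand_computed_binary_example(self):
        # TP=90, FN=10, TN=80, FP=20
        truth = ["pos"] * 100 + ["neg"] * 100
        pred = ["pos"] * 90 + ["neg"] * 10 + ["neg"] * 80 + ["pos"] * 20
        rep = compute_metrics(truth, pred, labels=["neg", "pos"], positive_class="pos")
        assert rep.sensitivity == pytest.approx(0.90)
        assert rep.specificity == pytest.approx(0.80)
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.score == pytest.approx(0.85)
        assert rep.f1 == pytest.approx(180 / 210)

    def test_perfect_predictions(self):
        rep = compute_metrics(["a", "b", "a"], ["a", "b", "a"], labels=["a", "b"],
                              positive_class="b")
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.f1, rep.score) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_positive_degenerate_classifier(self):
        truth = ["pos"] * 50 + ["neg"] * 50
        rep = compute_metrics(truth, ["pos"] * 100, labels=["neg", "pos"],
                              positive_class="pos")
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0
        assert rep.score == pytest.approx(0.5)

    def test_confusion_against_sklearn_oracle(self, rng):
        labels = ["x", "y", "z"]
        for _ in range(20):
            truth = rng.choice(labels, size=50)
            pred = rng.choice(labels, size=50)
            rep = compute_metrics(truth, pred, labels=labels)
            np.testing.assert_array_equal(
                rep.confusion, sk_confusion(truth, pred, labels=labels))

    def test_absent_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="absent from truth"):
            rep = compute_metrics(["x", "x", "y"], ["x", "y", "y"], labels=["x", "y", "z"])
        assert np.isfinite(rep.sensitivity)

    def test_empty_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_metrics([], [])


class TestWeightedAccuracy:
    def test_equal_weights_reduce_to_accuracy(self, rng):
        cm = rng.integers(0, 20, size=(3, 3))
        cm[0, 0] += 1
        assert weighted_accuracy(cm, [1, 1, 1]) == pytest.approx(np.trace(cm) / cm.sum())

    def test_diagonal_matrix_is_perfect(self):
        assert weighted_accuracy(np.diag([5, 2, 9]), [5, 3, 1]) == 1.0

    def test_hand_computed_example(self):
        cm = np.array([[3, 1, 0], [1, 1, 0], [0, 0, 4]])
        assert weighted_accuracy(cm, [5, 3, 1]) == pytest.approx(22 / 30)

    def test_zero_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            weighted_accuracy(np.zeros((3, 3)), [1, 1, 1])


def test_cross_entropy_matches_manual_log_loss(rng):
    logits = rng.normal(size=(6, 3))
    y = rng.integers(0, 3, size=6)
    loss = float(cross_entropy(Tensor(logits), one_hot(y, 3)).data)
    p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
    np.testing.assert_allclose(loss, -np.mean(np.log(p[np.arange(6), y])), atol=1e-9)


def test_adam_descends_simple_quadratic():
    x = Tensor(np.array([5.0]), requires_grad=True)
    opt = Adam({"x": x}, lr=0.1)
    for _ in range(200):
        loss = (x * x).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert abs(float(x.data[0])) < 0.1


class TestTrainLoop:
    @pytest.fixture(scope="class")
    def toy_problem(self, tiny_model_cfg):
        # two blobs of constant images: trivially separable
        rng = np.random.default_rng(0)
        X0 = rng.normal(size=(12, 64, 64, 3)) * 0.1 - 1.0
        X1 = rng.normal(size=(12, 64, 64, 3)) * 0.1 + 1.0
        X = np.concatenate([X0, X1]).astype(np.float32)
        y = np.array([0] * 12 + [1] * 12)
        idx = rng.permutation(24)
        return (X[idx[:16]], y[idx[:16]]), (X[idx[16:]], y[idx[16:]])

    def test_early_stopping_restores_best_epoch(self, tiny_model_cfg, toy_problem):
        train_set, val_set = toy_problem
        model = TwoStreamViT(tiny_model_cfg)
        cfg = TrainConfig(lr=0.008, batch_size=8, max_epochs=12, patience=3, seed=0)
        hist = train(model, train_set, val_set, cfg)
        assert hist["best_epoch"] <= len(hist["val_acc"]) - 1
        assert len(hist["val_acc"]) <= cfg.max_epochs
        # stopping fires within patience epochs of the best epoch
        assert len(hist["val_acc"]) - 1 - hist["best_epoch"] <= cfg.patience
        # restored weights reproduce the logged best validation accuracy
        assert evaluate_accuracy(model, *val_set) == pytest.approx(hist["best_val_acc"])
        assert hist["best_val_acc"] == pytest.approx(max(hist["val_acc"]))

    def test_separable_toy_problem_is_learned(self, tiny_model_cfg, toy_problem):
        train_set, val_set = toy_problem
        model = TwoStreamViT(tiny_model_cfg)
        hist = train(model, train_set, val_set,
                     TrainConfig(lr=0.008, batch_size=8, max_epochs=30, patience=10, seed=1))
        assert hist["best_val_acc"] >= 0.9

    def test_nan_loss_aborts_with_diagnostic(self, tiny_model_cfg, toy_problem):
        train_set, val_set = toy_problem
        model = TwoStreamViT(tiny_model_cfg)
        with pytest.raises(RuntimeError, match="loss"):
            train(model, train_set, val_set,
                  TrainConfig(lr=1e12, batch_size=8, max_epochs=10, patience=2, seed=0))

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(lr=-1.0)
        with pytest.raises(ConfigurationError):
            TrainConfig(patience=400, max_epochs=400)
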