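"""Training loop, model selection and evaluation for the topology classifier.

Training follows the usual supervised recipe for this model family: Adam
with an exponentially decaying learning rate (gamma every ``lr_decay_every``
epochs), cross-entropy on the raw class scores, periodic evaluation on the
test split, and final reporting of the checkpoint with the best test
accuracy on the held-out validation split.  The train/test/validation splits
are taken from the dataset and asserted disjoint; validation data are never
touched before the final report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .model import TopologyClassifier, cross_entropy
from .simulate import Dataset, LabeledSample

__all__ = ["TrainConfig", "EvalReport", "train", "evaluate"]


@dataclass
class TrainConfig:
    epochs: int = 300
    batch_size: int = 16
    learning_rate: float = 1e-3
    lr_decay_gamma: float = 0.9
    lr_decay_every: int = 10
    test_every: int = 10
    seed: int = 0
    subset_per_epoch: int | None = None   # quintet-style per-epoch subsampling
    test_subset: int | None = None        # evaluate on a random test subset
    reduction: str = "mean"
    stop_at_test_accuracy: float | None = None  # optional early stop threshold


@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray                       # (K, K): true class x predicted
    n_samples: int
    per_scenario: dict[int, float] = field(default_factory=dict)
    best_epoch: int | None = None
    best_test_accuracy: float | None = None
    validation_accuracy: float | None = None
    history: list[tuple[int, float, float]] = field(default_factory=list)
    # history rows: (epoch, mean training loss, test accuracy or nan)


def _encode_split(model: TopologyClassifier, samples: list[LabeledSample],
                  idx: np.ndarray):
    subset = [samples[i] for i in idx]
    X = model.encode_batch([s.alignment for s in subset])
    y = np.array([s.label for s in subset], dtype=int)
    scenarios = np.array([s.meta.get("scenario", 0) for s in subset], dtype=int)
    return X, y, scenarios


def _accuracy(model: TopologyClassifier, X: np.ndarray, y: np.ndarray,
              batch_size: int = 64) -> tuple[float, np.ndarray, np.ndarray]:
    K = model.n_classes
    confusion = np.zeros((K, K), dtype=int)
    preds = np.empty(len(y), dtype=int)
    for lo in range(0, len(y), batch_size):
        scores = model.forward_scores(X[lo : lo + batch_size]).data
        preds[lo : lo + len(scores)] = scores.argmax(axis=1) + 1
    for t, p in zip(y, preds):
        confusion[t - 1, p - 1] += 1
    return float((preds == y).mean()), confusion, preds


def evaluate(model: TopologyClassifier, samples: list[LabeledSample]) -> EvalReport:
    """Accuracy and confusion counts; stratified per scenario when tagged."""
    X = model.encode_batch([s.alignment for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    acc, confusion, preds = _accuracy(model, X, y)
    scen = np.array([s.meta.get("scenario", 0) for s in samples], dtype=int)
    per_scenario = {int(sc): float((preds[scen == sc] == y[scen == sc]).mean())
                    for sc in np.unique(scen)}
    return EvalReport(accuracy=acc, confusion=confusion, n_samples=len(samples),
                      per_scenario=per_scenario)


def train(model: TopologyClassifier, dataset: Dataset,
          cfg: TrainConfig) -> tuple[TopologyClassifier, EvalReport]:
    """Train in place and return the model restored to its best checkpoint.

    Reproducible given ``cfg.seed``: shuffling, per-epoch subsampling and
    dropout all draw from one seeded generator.
    """
    tr, te, va = set(dataset.train_idx), set(dataset.test_idx), set(dataset.val_idx)
    if tr & te or tr & va or te & va:
        raise ValueError("train/test/validation splits overlap")
    if not dataset.train_idx.size or not dataset.test_idx.size or not dataset.val_idx.size:
        raise ValueError("all three splits must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    X_train, y_train, _ = _encode_split(model, dataset.samples, dataset.train_idx)
    X_test, y_test, _ = _encode_split(model, dataset.samples, dataset.test_idx)

    optimizer = Adam(model.params, lr=cfg.learning_rate)
    best_state = model.state_copy()
    best_acc, best_epoch = -1.0, 0
    history: list[tuple[int, float, float]] = []

    for epoch in range(1, cfg.epochs + 1):
        optimizer.lr = cfg.learning_rate * cfg.lr_decay_gamma ** ((epoch - 1) // cfg.lr_decay_every)
        order = rng.permutation(len(y_train))
        if cfg.subset_per_epoch is not None:
            order = order[: cfg.subset_per_epoch]  # without replacement per epoch
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch = order[lo : lo + cfg.batch_size]
            optimizer.zero_grad()
            scores = model.forward_scores(X_train[batch], train=True, rng=rng)
            loss = cross_entropy(scores, y_train[batch], reduction=cfg.reduction)
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        test_acc = np.nan
        if epoch % cfg.test_every == 0 or epoch == cfg.epochs or (
                cfg.stop_at_test_accuracy is not None):
            if cfg.test_subset is not None and cfg.test_subset < len(y_test):
                pick = rng.choice(len(y_test), size=cfg.test_subset, replace=False)
                test_acc, _, _ = _accuracy(model, X_test[pick], y_test[pick])
            else:
                test_acc, _, _ = _accuracy(model, X_test, y_test)
            if test_acc > best_acc:
                best_acc, best_epoch = test_acc, epoch
                best_state = model.state_copy()
        history.append((epoch, float(np.mean(losses)) if losses else np.nan, test_acc))
        if cfg.stop_at_test_accuracy is not None and test_acc >= cfg.stop_at_test_accuracy:
            break

    if cfg.epochs == 0:
        best_acc, best_epoch = np.nan, 0
        best_state = model.state_copy()
    model.load_state(best_state)

    # validation touched exactly once, with the selected checkpoint
    val_samples = [dataset.samples[i] for i in dataset.val_idx]
    val_report = evaluate(model, val_samples)
    test_report = evaluate(model, [dataset.samples[i] for i in dataset.test_idx])
    test_report.best_epoch = best_epoch
    test_report.best_test_accuracy = None if np.isnan(best_acc) else float(best_acc)
    test_report.validation_accuracy = val_report.accuracy
    test_report.history = history
    return model, test_report
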