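"""Training recipe, AAMI interpatient evaluation and the sklearn estimator.

Training follows a fixed recipe: Adam, cross-entropy loss, batch size
16, initial learning rate 1e-3 decayed by 10x every 20 epochs.  The
evaluation protocol is strict interpatient AAMI scoring: the model is
scored beat by beat on the untouched DS2 test partition, and per-class
sensitivity (Sen), positive predictivity (Ppr) and F1 are derived
one-vs-rest from the 4x4 confusion matrix:

    Sen = 100 * TP / (TP + FN)          Ppr = 100 * TP / (TP + FP)
    F1  = 2 * Sen * Ppr / (Sen + Ppr)   Acc = 100 * trace / total
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import BeatDataset
from .io import TARGET_CLASSES
from .model import RACNN
from .nn import Adam, StepLR, Tensor, cross_entropy

__all__ = ["TrainConfig", "EvalReport", "TrainingError", "train", "evaluate",
           "predict_labels", "compute_metrics", "confusion_matrix", "f1_score",
           "RACNNClassifier"]


def f1_score(sen: float, ppr: float) -> float:
    """Harmonic mean of sensitivity and positive predictivity (percent)."""
    if sen < 0 or ppr < 0:
        raise ValueError("rates must be non-negative")
    if sen + ppr == 0:
        return 0.0
    return 2.0 * sen * ppr / (sen + ppr)

_CLASS_INDEX = {c: i for i, c in enumerate(TARGET_CLASSES)}


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """The training recipe; defaults are the published settings."""

    initial_lr: float = 1e-3
    lr_step_epochs: int = 20
    lr_gamma: float = 0.1
    batch_size: int = 16
    epochs: int = 60
    seed: int = 0

    def __post_init__(self):
        if min(self.initial_lr, self.batch_size, self.epochs,
               self.lr_step_epochs) <= 0:
            raise ValueError("all training parameters must be positive")

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during 1-based `epoch`."""
        return StepLR(None, self.initial_lr, self.lr_step_epochs,
                      self.lr_gamma).lr_at(epoch)


def _labels_to_int(labels: np.ndarray) -> np.ndarray:
    return np.array([_CLASS_INDEX[str(c)] for c in labels], dtype=np.int64)


def _fit_loop(model: RACNN, X: np.ndarray, yi: np.ndarray,
              config: TrainConfig, log: callable = None) -> list[float]:
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.initial_lr)
    schedule = StepLR(optimizer, config.initial_lr,
                      config.lr_step_epochs, config.lr_gamma)
    model.train()
    history: list[float] = []
    n = X.shape[0]
    for epoch in range(1, config.epochs + 1):
        lr = schedule.set_epoch(epoch)
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            loss = cross_entropy(model(Tensor(X[idx])), yi[idx])
            if not np.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {lo // config.batch_size}"
                    f" (lr={lr:g}); check input scaling or lower the rate")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log:
            log(f"epoch {epoch:3d}  lr {lr:g}  loss {history[-1]:.4f}")
    return history


def train(model: RACNN, dataset: BeatDataset, config: TrainConfig | None = None,
          log: callable = None) -> list[float]:
    """Train `model` on a DS1 dataset in place; returns per-epoch mean loss."""
    config = config or TrainConfig()
    if len(dataset) == 0:
        raise TrainingError("empty training dataset")
    return _fit_loop(model, dataset.images, _labels_to_int(dataset.labels),
                     config, log)


def predict_labels(model: RACNN, images: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    """Deterministic class predictions (eval mode) for stacked images."""
    model.eval()
    preds = []
    for lo in range(0, images.shape[0], batch_size):
        scores = model(Tensor(images[lo : lo + batch_size]))
        preds.append(np.argmax(scores.data, axis=1))
    return np.array([TARGET_CLASSES[i] for i in np.concatenate(preds)])


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """4x4 confusion matrix, rows = true class, columns = predicted (N,S,V,F)."""
    cm = np.zeros((4, 4), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        cm[_CLASS_INDEX[str(t)], _CLASS_INDEX[str(p)]] += 1
    return cm


def compute_metrics(confusion: np.ndarray) -> dict:
    """One-vs-rest Sen/Ppr/F1 per class and overall Acc, in percent.

    Zero-denominator cases (a class absent from truth or predictions)
    yield 0 with a warning rather than NaN.
    """
    cm = np.asarray(confusion)
    if cm.shape != (4, 4):
        raise ValueError("confusion matrix must be 4x4 (N, S, V, F)")
    if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.number):
        raise ValueError("confusion matrix entries must be non-negative numbers")
    total = cm.sum()
    per_class = {}
    counts = {}
    for i, c in enumerate(TARGET_CLASSES):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        counts[c] = {"TP": int(tp), "FN": int(fn), "FP": int(fp), "TN": int(tn)}
        sen = _safe_pct(tp, tp + fn, f"Sen({c})")
        ppr = _safe_pct(tp, tp + fp, f"Ppr({c})")
        per_class[c] = {"Sen": sen, "Ppr": ppr, "F1": f1_score(sen, ppr)}
    acc = _safe_pct(np.trace(cm), total, "Acc")
    return {"acc": acc, "per_class": per_class, "counts": counts}


def _safe_pct(num, den, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return 100.0 * float(num) / float(den)


@dataclass
class EvalReport:
    """Confusion matrix plus derived per-class and overall metrics."""

    confusion: np.ndarray
    per_class: dict = field(default=None)
    acc: float = None
    counts: dict = field(default=None)

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        m = compute_metrics(self.confusion)
        self.per_class = m["per_class"]
        self.acc = m["acc"]
        self.counts = m["counts"]

    def to_json(self) -> str:
        return json.dumps({"acc": self.acc, "per_class": self.per_class,
                           "counts": self.counts,
                           "confusion": self.confusion.tolist()}, indent=1)

    def to_text(self) -> str:
        lines = [f"Acc {self.acc:.1f}%",
                 "class    Sen     Ppr      F1"]
        for c in TARGET_CLASSES:
            p = self.per_class[c]
            lines.append(f"{c}    {p['Sen']:7.2f} {p['Ppr']:7.2f} {p['F1']:7.2f}")
        return "\n".join(lines)

    def confusion_csv(self) -> str:
        header = "," + ",".join(TARGET_CLASSES)
        rows = [f"{c}," + ",".join(str(v) for v in row)
                for c, row in zip(TARGET_CLASSES, self.confusion)]
        return "\n".join([header] + rows) + "\n"


def evaluate(model: RACNN, dataset: BeatDataset) -> EvalReport:
    """Beat-by-beat evaluation on an unaugmented test dataset."""
    if dataset.augmented:
        raise ValueError("evaluation requires an unaugmented dataset "
                         "(the test protocol forbids augmented beats)")
    preds = predict_labels(model, dataset.images)
    return EvalReport(confusion=confusion_matrix(dataset.labels, preds))


class RACNNClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping the RA-CNN and its training recipe.

    Accepts stacked images X of shape (n, 3, input_size, input_size) and
    string (or integer) labels y.  Fitted attributes: ``model_`` (the
    trained network), ``classes_``, ``loss_history_``.
    """

    def __init__(self, input_size: int = 224, stem_channels: int = 16,
                 groups: int = 2, epochs: int = 60, batch_size: int = 16,
                 initial_lr: float = 1e-3, lr_step_epochs: int = 20,
                 lr_gamma: float = 0.1, seed: int = 0,
                 use_rblock: bool = True, use_ablock: bool = True,
                 channel_att: bool = True, spatial_att: bool = True,
                 top_skip: bool = True, middle_layer: bool = True):
        self.input_size = input_size
        self.stem_channels = stem_channels
        self.groups = groups
        self.epochs = epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.lr_step_epochs = lr_step_epochs
        self.lr_gamma = lr_gamma
        self.seed = seed
        self.use_rblock = use_rblock
        self.use_ablock = use_ablock
        self.channel_att = channel_att
        self.spatial_att = spatial_att
        self.top_skip = top_skip
        self.middle_layer = middle_layer

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != 3 or X.shape[2] != self.input_size \
                or X.shape[3] != self.input_size:
            raise ValueError(f"X must be (n, 3, {self.input_size}, "
                             f"{self.input_size}), got {X.shape}")
        return X

    def build_model(self, n_classes: int) -> RACNN:
        return RACNN(n_classes=n_classes, input_size=self.input_size,
                     stem_channels=self.stem_channels, groups=self.groups,
                     seed=self.seed, use_rblock=self.use_rblock,
                     use_ablock=self.use_ablock, channel_att=self.channel_att,
                     spatial_att=self.spatial_att, top_skip=self.top_skip,
                     middle_layer=self.middle_layer)

    def fit(self, X, y, log: callable = None) -> "RACNNClassifier":
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([class_index[c] for c in y], dtype=np.int64)
        self.model_ = self.build_model(len(self.classes_))
        config = TrainConfig(initial_lr=self.initial_lr,
                             lr_step_epochs=self.lr_step_epochs,
                             lr_gamma=self.lr_gamma, batch_size=self.batch_size,
                             epochs=self.epochs, seed=self.seed)
        self.loss_history_ = _fit_loop(self.model_, X, yi, config, log)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        self.model_.eval()
        out = []
        for lo in range(0, X.shape[0], 64):
            out.append(self.model_(Tensor(X[lo : lo + 64])).data)
        return np.concatenate(out)

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]
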