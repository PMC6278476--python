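"""Discriminant models for variety classification from mean spectra.

Three models are supported on full or selected wavelengths:

* RBF-kernel SVM with a (c, g) grid search by stratified cross-validation;
* one-vs-rest logistic regression with configurable penalty and solver;
* a 1-D deep convolutional network: ``num_convs`` modules of two 3-wide
  convolutions (filters doubling per module, 32 in the first by default)
  each followed by batch normalization and ELU, a 2-wide max pool per
  module, then two dense layers, batch normalization + ELU after the first
  only, and a softmax output. Training minimizes cross-entropy with SGD
  (learning rate 0.001, momentum 0.9, batch size 256 by default).

SVM and LR inputs are z-scored with training-set statistics (both are
scale-sensitive); the network consumes reflectance directly and lets batch
normalization handle scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import InvalidArgumentError
from .network import (
    BatchNorm,
    Conv1d,
    Dense,
    Elu,
    Flatten,
    MaxPool1d,
    Sequential,
    softmax,
    softmax_cross_entropy_grad,
)
from .spectra import DatasetSplit, SpectraTable

__all__ = [
    "SvmConfig",
    "LrConfig",
    "DcnnConfig",
    "EvalReport",
    "elu",
    "cross_entropy",
    "train_svm",
    "train_lr",
    "build_dcnn",
    "train_dcnn",
    "evaluate",
    "Dcnn",
]

# solver/penalty compatibility for one-vs-rest logistic regression
_LR_SOLVERS = {
    "newton-cg": {"L2"},
    "lbfgs": {"L2"},
    "liblinear": {"L1", "L2"},
    "sag": {"L2"},
    "saga": {"L1", "L2"},
}


def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x >= 0, alpha(e^x - 1) for x < 0."""
    if alpha <= 0:
        raise InvalidArgumentError("alpha must be positive")
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0)))
    return float(out) if out.ndim == 0 else out


def cross_entropy(p, q) -> float:
    """Cross entropy -sum p(x) log q(x); q is clipped to [1e-12, 1]."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise InvalidArgumentError("p and q must have the same length")
    q = np.clip(q, 1e-12, 1.0)
    return float(-np.sum(p * np.log(q)))


@dataclass
class SvmConfig:
    """RBF-SVM penalty/kernel parameters and their search grids (powers of 10)."""

    c: float | None = None
    g: float | None = None
    grid_c: tuple[float, ...] = tuple(10.0**e for e in range(-2, 9))
    grid_g: tuple[float, ...] = tuple(10.0**e for e in range(-8, 3))
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.c is not None and self.c <= 0:
            raise InvalidArgumentError("c must be positive")
        if self.g is not None and self.g <= 0:
            raise InvalidArgumentError("g must be positive")


@dataclass
class LrConfig:
    """One-vs-rest logistic regression hyper-parameters."""

    pi: str = "L2"
    c_prime: float = 100.0
    optimize_algo: str = "liblinear"

    def __post_init__(self) -> None:
        if self.c_prime <= 0:
            raise InvalidArgumentError("c_prime must be positive")
        if self.optimize_algo not in _LR_SOLVERS:
            raise InvalidArgumentError(f"unknown solver {self.optimize_algo!r}")
        if self.pi not in _LR_SOLVERS[self.optimize_algo]:
            raise InvalidArgumentError(
                f"penalty {self.pi!r} not supported by solver {self.optimize_algo!r}"
            )


@dataclass
class DcnnConfig:
    """Architecture and training budget of the 1-D convolutional network."""

    num_convs: int = 4
    num_first_kernels: int = 32
    epoch: int = 93
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 256
    elu_alpha: float = 1.0
    fc_hidden: int = 256

    def __post_init__(self) -> None:
        if self.num_convs < 1:
            raise InvalidArgumentError("num_convs must be >= 1")
        if self.epoch < 0:
            raise InvalidArgumentError("epoch must be >= 0")


@dataclass
class EvalReport:
    """Accuracies and confusion counts of one trained model."""

    train_accuracy: float | None
    test_accuracy: float | None
    confusion: np.ndarray
    classes: np.ndarray
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
            "classes": [int(c) for c in self.classes],
            "confusion": np.asarray(self.confusion).tolist(),
            "config": self.config,
        }
        text = json.dumps(payload, indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def _accuracy_and_confusion(y_true, y_pred, classes):
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    total = conf.sum()
    acc = float(np.trace(conf) / total) if total else float("nan")
    return acc, conf


def evaluate(model, table: SpectraTable) -> EvalReport:
    """Confusion matrix and accuracy of ``model`` on a spectra table.

    Accuracy is exactly trace(confusion) / total. The model must have been
    trained on the same band grid.
    """
    n_bands = getattr(model, "n_bands", None)
    if n_bands is not None and n_bands != table.n_bands:
        raise InvalidArgumentError(
            f"model expects {n_bands} bands, table has {table.n_bands}"
        )
    y_pred = model.predict(table.spectra)
    classes = getattr(model, "classes_", None)
    if classes is None:
        classes = np.unique(np.concatenate([table.labels, y_pred]))
    classes = np.asarray(classes)
    acc, conf = _accuracy_and_confusion(table.labels, y_pred, classes)
    return EvalReport(None, acc, conf, classes)


def _full_report(model, split: DatasetSplit, config: dict) -> EvalReport:
    train_rep = evaluate(model, split.train)
    test_rep = (
        evaluate(model, split.test) if len(split.test) else
        EvalReport(None, None, np.zeros_like(train_rep.confusion), train_rep.classes)
    )
    return EvalReport(
        train_accuracy=train_rep.test_accuracy,
        test_accuracy=test_rep.test_accuracy,
        confusion=test_rep.confusion,
        classes=train_rep.classes,
        config=config,
    )


class _SklearnModel:
    """Thin predict wrapper recording the band count the model was fit on."""

    def __init__(self, pipeline, n_bands: int) -> None:
        self.pipeline = pipeline
        self.n_bands = n_bands

    @property
    def classes_(self):
        return self.pipeline.classes_

    def predict(self, X):
        return self.pipeline.predict(np.asarray(X))

    def predict_proba(self, X):
        proba = self.pipeline.predict_proba(np.asarray(X))
        return proba / proba.sum(axis=1, keepdims=True)


def train_svm(
    split: DatasetSplit, config: SvmConfig | None = None, seed: int = 0
):
    """Grid-search an RBF SVM on the training set and report both accuracies.

    The (c, g) grid is searched by stratified cross-validation on the
    training set; the best pair is refit on all of it. Features are z-scored
    with training statistics inside the pipeline. If ``config.c``/``config.g``
    are set, the grid collapses to that single cell.
    """
    config = config or SvmConfig()
    y = split.train.labels
    if np.unique(y).size < 2:
        raise InvalidArgumentError("training set must contain at least 2 classes")
    grid_c = (config.c,) if config.c is not None else config.grid_c
    grid_g = (config.g,) if config.g is not None else config.grid_g
    min_class = int(np.unique(y, return_counts=True)[1].min())
    folds = max(2, min(config.cv_folds, min_class))
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    if len(grid_c) == 1 and len(grid_g) == 1:
        pipe.set_params(svc__C=grid_c[0], svc__gamma=grid_g[0])
        pipe.fit(split.train.spectra, y)
        best_c, best_g = grid_c[0], grid_g[0]
        model = _SklearnModel(pipe, split.train.n_bands)
    else:
        search = GridSearchCV(
            pipe,
            {"svc__C": list(grid_c), "svc__gamma": list(grid_g)},
            cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
            n_jobs=None,
        )
        search.fit(split.train.spectra, y)
        best_c = search.best_params_["svc__C"]
        best_g = search.best_params_["svc__gamma"]
        model = _SklearnModel(search.best_estimator_, split.train.n_bands)
    report = _full_report(model, split, {"model": "svm", "c": best_c, "g": best_g})
    return model, report


def train_lr(split: DatasetSplit, config: LrConfig | None = None):
    """Fit one-vs-rest logistic regression; class = argmax of the per-class
    logistic probabilities (normalized to sum to 1)."""
    config = config or LrConfig()
    y = split.train.labels
    if np.unique(y).size < 2:
        raise InvalidArgumentError("training set must contain at least 2 classes")
    base = LogisticRegression(
        l1_ratio=1.0 if config.pi == "L1" else 0.0,
        C=config.c_prime,
        solver=config.optimize_algo,
        max_iter=2000,
    )
    pipe = Pipeline([("scale", StandardScaler()), ("ovr", OneVsRestClassifier(base))])
    pipe.fit(split.train.spectra, y)
    model = _SklearnModel(pipe, split.train.n_bands)
    report = _full_report(
        model,
        split,
        {"model": "lr", "pi": config.pi, "c_prime": config.c_prime,
         "optimize_algo": config.optimize_algo},
    )
    return model, report


class Dcnn:
    """The 1-D convolutional network plus its architecture description."""

    def __init__(self, net: Sequential, config: DcnnConfig, n_bands: int,
                 n_classes: int, feature_lengths: list[int], filters: list[int]) -> None:
        self.net = net
        self.config = config
        self.n_bands = n_bands
        self.n_classes = n_classes
        self.feature_lengths = feature_lengths  # input length after each pool
        self.filters = filters
        self.classes_: np.ndarray | None = None

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities (softmax of the final dense layer)."""
        self.net.train_mode(training)
        logits = self.net.forward(np.asarray(X, np.float64).reshape(len(X), 1, self.n_bands))
        return softmax(logits)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = self.predict_proba(X).argmax(axis=1)
        classes = self.classes_ if self.classes_ is not None else np.arange(1, self.n_classes + 1)
        return np.asarray(classes)[idx]

    def num_params(self) -> int:
        return self.net.num_params()

    def summary(self) -> dict:
        return {
            "num_convs": self.config.num_convs,
            "num_first_kernels": self.config.num_first_kernels,
            "feature_lengths": self.feature_lengths,
            "filters": self.filters,
            "fc_hidden": self.config.fc_hidden,
            "n_bands": self.n_bands,
            "n_classes": self.n_classes,
            "n_parameters": self.num_params(),
        }


def build_dcnn(config: DcnnConfig, n_bands: int, n_classes: int, seed: int = 0) -> Dcnn:
    """Assemble the spectral 1-D CNN.

    Module m (1-based) holds two 3-wide convolutions with
    ``num_first_kernels * 2**(m-1)`` filters, each followed by batch
    normalization and ELU, then a 2-wide max pool (floor on odd lengths).
    After flattening: dense(fc_hidden) + BN + ELU, then dense(n_classes) with
    no BN/ELU; the output is a softmax. Raises if pooling collapses the
    sequence to length 0.
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    length = n_bands
    channels = 1
    feature_lengths = [n_bands]
    filters: list[int] = []
    for m in range(config.num_convs):
        f = config.num_first_kernels * (2**m)
        filters.append(f)
        for _ in range(2):
            layers.append(Conv1d(channels, f, kernel=3, rng=rng))
            layers.append(BatchNorm(f))
            layers.append(Elu(config.elu_alpha))
            channels = f
        length //= 2
        if length < 1:
            raise InvalidArgumentError(
                f"{n_bands} bands collapse to zero length after {m + 1} poolings"
            )
        layers.append(MaxPool1d())
        feature_lengths.append(length)
    layers.append(Flatten())
    layers.append(Dense(channels * length, config.fc_hidden, rng=rng))
    layers.append(BatchNorm(config.fc_hidden))
    layers.append(Elu(config.elu_alpha))
    layers.append(Dense(config.fc_hidden, n_classes, rng=rng))
    return Dcnn(Sequential(layers), config, n_bands, n_classes, feature_lengths, filters)


def train_dcnn(split: DatasetSplit, config: DcnnConfig | None = None, seed: int = 0):
    """Train the 1-D CNN by SGD with momentum on mini-batches of mean spectra.

    Minimizes the softmax cross-entropy for ``config.epoch`` full passes.
    Weight initialization and batch shuffling are seeded, so the same seed
    reproduces the same report. ``epoch=0`` evaluates the untrained network.
    A batch size exceeding the training-set size is shrunk with a warning.
    """
    config = config or DcnnConfig()
    X = split.train.spectra
    y = split.train.labels
    n = len(X)
    if n == 0:
        raise InvalidArgumentError("training set is empty")
    classes = np.unique(y)
    n_classes = classes.size
    class_index = {c: i for i, c in enumerate(classes)}
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), [class_index[c] for c in y]] = 1.0

    ss = np.random.SeedSequence(seed)
    init_seed, shuffle_seed = ss.spawn(2)
    model = build_dcnn(config, split.train.n_bands, n_classes,
                       seed=int(init_seed.generate_state(1)[0] % (2**31)))
    model.classes_ = classes
    rng = np.random.default_rng(shuffle_seed)

    batch = config.batch_size
    if batch > n:
        warnings.warn(
            f"batch size {batch} exceeds training-set size {n}; using {n}",
            RuntimeWarning,
            stacklevel=2,
        )
        batch = n
    Xin = X.reshape(n, 1, -1)
    for _ in range(config.epoch):
        order = rng.permutation(n)
        model.net.train_mode(True)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            model.net.zero_grad()
            logits = model.net.forward(Xin[idx])
            _, grad = softmax_cross_entropy_grad(logits, onehot[idx])
            model.net.backward(grad)
            model.net.sgd_step(config.learning_rate, config.momentum)
    model.net.train_mode(False)
    report = _full_report(
        model,
        split,
        {
            "model": "dcnn",
            "num_convs": config.num_convs,
            "num_first_kernels": config.num_first_kernels,
            "epoch": config.epoch,
            "learning_rate": config.learning_rate,
            "momentum": config.momentum,
            "batch_size": batch,
            "fc_hidden": config.fc_hidden,
        },
    )
    return model, report
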