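"""Dense burst-shape classifiers and their training harness.

Three presets (``dtct1``/``dtct2``/``dtct3``) share one architecture: a
flat signal window feeds five fully connected ReLU layers, a dropout
layer, and a two-unit softmax head trained with sparse categorical
cross-entropy under the adamax optimizer.  The network and optimizer are
implemented directly on NumPy so training is dependency-free and
bit-reproducible per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats


class TrainingError(RuntimeError):
    """The training split does not contain both classes."""


@dataclass
class ClassifierConfig:
    name: str = "custom"
    input_len: int = 1000
    hidden_widths: tuple[int, ...] = (256, 128, 64, 32, 16)
    dropout_rate: float = 0.5
    batch_size: int = 32
    epochs: int = 20
    optimizer: str = "adamax"
    loss: str = "sparse_categorical_crossentropy"
    train_frac: float = 0.8
    triplicate_positives: bool = False
    standardize: bool = False
    n_repetitions: int = 100
    learning_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_len < 1:
            raise ValueError("input_len must be >= 1")
        if not self.hidden_widths or any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden_widths must be positive")
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.batch_size < 1 or self.epochs < 1 or self.n_repetitions < 1:
            raise ValueError("batch_size, epochs and n_repetitions must be >= 1")

    @classmethod
    def preset(cls, name: str, **overrides) -> "ClassifierConfig":
        """Named presets: 4 s windows / 6 epochs (dtct1), 1 s windows with
        positive triplication / 20 epochs (dtct2), 1 s windows, batch 16 /
        35 epochs (dtct3)."""
        presets = {
            "dtct1": dict(input_len=4001, batch_size=32, epochs=6, triplicate_positives=False),
            "dtct2": dict(input_len=1000, batch_size=32, epochs=20, triplicate_positives=True),
            "dtct3": dict(input_len=1000, batch_size=16, epochs=35, triplicate_positives=False),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        kwargs = dict(presets[name])
        kwargs.update(overrides)
        return cls(name=name, **kwargs)


@dataclass
class LabeledWindowSet:
    """Signal windows with binary burst labels and per-sample provenance."""

    windows: np.ndarray
    labels: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.windows.ndim != 2:
            raise ValueError("windows must be a 2-D matrix")
        if self.labels.shape != (self.windows.shape[0],):
            raise ValueError("labels length must match number of windows")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")
        if not self.provenance:
            self.provenance = [""] * self.windows.shape[0]
        if len(self.provenance) != self.windows.shape[0]:
            raise ValueError("provenance length must match number of windows")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def input_len(self) -> int:
        return self.windows.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledWindowSet":
        return LabeledWindowSet(
            self.windows[indices],
            self.labels[indices],
            [self.provenance[i] for i in indices],
        )


@dataclass
class TrainingReport:
    per_rep_accuracy: list[float]
    per_rep_auc: list[float]
    mean_train_accuracy_curve: np.ndarray
    mean_test_accuracy_curve: np.ndarray
    mean_train_loss_curve: np.ndarray
    mean_test_loss_curve: np.ndarray


def split_train_test(
    dataset: LabeledWindowSet, train_frac: float, seed: int
) -> tuple[LabeledWindowSet, LabeledWindowSet]:
    """Seeded random partition; the training size rounds half away from
    zero, the test set takes the remainder."""
    n = len(dataset)
    if n < 2:
        raise ValueError("dataset must contain at least 2 samples")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    n_train = int(np.floor(n * train_frac + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return dataset.subset(perm[:n_train]), dataset.subset(perm[n_train:])


def triplicate_positives(train: LabeledWindowSet, seed: int = 0) -> LabeledWindowSet:
    """Each positive window appears three times (content untouched), the
    result reshuffled with the run seed."""
    pos = np.flatnonzero(train.labels == 1)
    idx = np.concatenate([np.arange(len(train)), pos, pos])
    idx = idx[np.random.default_rng(seed).permutation(idx.size)]
    return train.subset(idx)


class DenseNet:
    """Feed-forward net: input -> dense ReLU stack -> dropout -> 2-unit
    softmax."""

    def __init__(self, config: ClassifierConfig, seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        sizes = [config.input_len, *config.hidden_widths, 2]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization suits the ReLU stack
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def input_len(self) -> int:
        return self.config.input_len

    def _forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        acts = [X]
        a = X
        n_hidden = len(self.weights) - 1
        mask = None
        for i in range(n_hidden):
            a = np.maximum(a @ self.weights[i] + self.biases[i], 0.0)
            acts.append(a)
        p_drop = self.config.dropout_rate
        if dropout_rng is not None and p_drop > 0.0:
            mask = (dropout_rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
            a = a * mask
        logits = a @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, acts, mask

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_len:
            raise ValueError(f"window length {X.shape[1]} != model input_len {self.input_len}")
        if self.config.standardize:
            X = _standardize(X)
        probs, _, _ = self._forward(X)
        return probs

    def _backward(self, probs, acts, mask, y):
        """Gradients of mean sparse-categorical cross-entropy."""
        n = y.size
        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        grads_w: list[np.ndarray] = [None] * len(self.weights)  # type: ignore[list-item]
        grads_b: list[np.ndarray] = [None] * len(self.biases)  # type: ignore[list-item]
        top_in = acts[-1] if mask is None else acts[-1] * mask
        grads_w[-1] = top_in.T @ delta
        grads_b[-1] = delta.sum(axis=0)
        delta = delta @ self.weights[-1].T
        if mask is not None:
            delta = delta * mask
        for i in range(len(self.weights) - 2, -1, -1):
            delta = delta * (acts[i + 1] > 0.0)
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
        return grads_w, grads_b


class Adamax:
    """Adamax update rule (infinity-norm variant of Adam)."""

    def __init__(self, params: Sequence[np.ndarray], lr=0.002, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        scale = self.lr / (1.0 - self.beta1**self.t)
        for p, g, m, u in zip(params, grads, self.m, self.u):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            np.maximum(self.beta2 * u, np.abs(g), out=u)
            p -= scale * m / (u + self.eps)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.where(sd > 1e-12, sd, 1.0)


def build_classifier(config: ClassifierConfig, seed: int | None = None) -> DenseNet:
    """Freshly initialized network for the given config."""
    return DenseNet(config, seed=seed)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(y.size), y], 1e-12, 1.0)
    return float(-np.mean(np.log(p)))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic area under the ROC curve (ties averaged)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required to compute ROC AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class TrainResult:
    model: DenseNet
    accuracy: float
    auc: float
    train_accuracy_curve: np.ndarray
    test_accuracy_curve: np.ndarray
    train_loss_curve: np.ndarray
    test_loss_curve: np.ndarray


def train_once(dataset: LabeledWindowSet, config: ClassifierConfig, seed: int) -> TrainResult:
    """One reshuffle -> (optional triplication) -> full training cycle.

    Held-out metrics (accuracy and rank ROC AUC from the positive-class
    probability) and per-epoch learning/loss curves are computed on the
    test split after every epoch.
    """
    if dataset.input_len != config.input_len:
        raise ValueError(
            f"dataset window length {dataset.input_len} != config input_len {config.input_len}"
        )
    train, test = split_train_test(dataset, config.train_frac, seed)
    if config.triplicate_positives:
        train = triplicate_positives(train, seed=seed)
    if len(np.unique(train.labels)) < 2:
        raise TrainingError("training split contains a single class")

    model = build_classifier(config, seed=seed)
    X_tr, y_tr = train.windows, train.labels
    X_te, y_te = test.windows, test.labels
    if config.standardize:
        X_tr, X_te = _standardize(X_tr), _standardize(X_te)

    params = model.weights + model.biases
    opt = Adamax(params, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD20]))

    tr_acc = np.zeros(config.epochs)
    te_acc = np.zeros(config.epochs)
    tr_loss = np.zeros(config.epochs)
    te_loss = np.zeros(config.epochs)
    n = X_tr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            probs, acts, mask = model._forward(X_tr[batch], dropout_rng=rng)
            gw, gb = model._backward(probs, acts, mask, y_tr[batch])
            opt.step(params, gw + gb)
        p_tr, _, _ = model._forward(X_tr)
        p_te, _, _ = model._forward(X_te)
        tr_acc[epoch] = float((p_tr.argmax(axis=1) == y_tr).mean())
        te_acc[epoch] = float((p_te.argmax(axis=1) == y_te).mean())
        tr_loss[epoch] = _cross_entropy(p_tr, y_tr)
        te_loss[epoch] = _cross_entropy(p_te, y_te)

    p_te, _, _ = model._forward(X_te)
    accuracy = float((p_te.argmax(axis=1) == y_te).mean())
    auc = roc_auc(y_te, p_te[:, 1]) if len(np.unique(y_te)) == 2 else float("nan")
    return TrainResult(model, accuracy, auc, tr_acc, te_acc, tr_loss, te_loss)


def train_repeated(
    dataset: LabeledWindowSet, config: ClassifierConfig
) -> tuple[TrainingReport, DenseNet]:
    """``n_repetitions`` independent reshuffle-and-retrain cycles.

    The report aggregates per-repetition metrics and mean curves; the
    model from the last repetition is the one retained for application.
    """
    rep_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_repetitions)
    accs, aucs = [], []
    curves = None
    model = None
    for rep_seed in rep_seeds:
        res = train_once(dataset, config, seed=int(rep_seed))
        accs.append(res.accuracy)
        aucs.append(res.auc)
        cs = (res.train_accuracy_curve, res.test_accuracy_curve,
              res.train_loss_curve, res.test_loss_curve)
        curves = cs if curves is None else tuple(a + b for a, b in zip(curves, cs))
        model = res.model
    k = float(config.n_repetitions)
    report = TrainingReport(
        per_rep_accuracy=accs,
        per_rep_auc=aucs,
        mean_train_accuracy_curve=curves[0] / k,
        mean_test_accuracy_curve=curves[1] / k,
        mean_train_loss_curve=curves[2] / k,
        mean_test_loss_curve=curves[3] / k,
    )
    return report, model


def predict_window(model: DenseNet, window: Sequence[float]) -> tuple[float, float, int]:
    """Class probabilities and the binary label for one window.

    Returns ``(p_negative, p_positive, label)`` with the label positive
    exactly when the positive-class probability is at least as large.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size != model.input_len:
        raise ValueError(f"window length {w.size} != model input_len {model.input_len}")
    probs = model.predict_proba(w[None, :])[0]
    return float(probs[0]), float(probs[1]), int(probs[1] >= probs[0])


def save_model(model: DenseNet, path: str | Path) -> None:
    """Persist weights (npz) with a JSON config sidecar; round-trips
    bit-stably."""
    path = Path(path)
    arrays = {}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path.with_suffix(".npz"), **arrays)
    cfg = model.config
    sidecar = {
        "name": cfg.name,
        "input_len": cfg.input_len,
        "hidden_widths": list(cfg.hidden_widths),
        "dropout_rate": cfg.dropout_rate,
        "batch_size": cfg.batch_size,
        "epochs": cfg.epochs,
        "optimizer": cfg.optimizer,
        "loss": cfg.loss,
        "train_frac": cfg.train_frac,
        "triplicate_positives": cfg.triplicate_positives,
        "standardize": cfg.standardize,
        "n_repetitions": cfg.n_repetitions,
        "learning_rate": cfg.learning_rate,
        "seed": cfg.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> DenseNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    sidecar["hidden_widths"] = tuple(sidecar["hidden_widths"])
    config = ClassifierConfig(**sidecar)
    model = DenseNet(config)
    with np.load(path.with_suffix(".npz")) as data:
        for i in range(len(model.weights)):
            model.weights[i] = data[f"W{i}"]
            model.biases[i] = data[f"b{i}"]
    return model
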