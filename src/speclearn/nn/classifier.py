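"""Training loop and the sklearn-style CNN estimator.

Training minimises class-weighted cross-entropy with Adam, evaluates the
validation subset every epoch and checkpoints parameters only when
validation accuracy improves; the returned model is always the best
checkpoint.  Layers whose spec is flagged non-trainable are bitwise
untouched, which is the contract transfer and cumulative learning rely
on.  When a frozen prefix of the network is deterministic (e.g. the whole
convolutional stack under ``freeze_all_conv``), its activations are
computed once per dataset and cached, so head-only retraining costs a
fraction of a full pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .architectures import build_architecture
from .network import (
    Adam,
    ModelState,
    Network,
    class_weights,
    init_parameters,
    replace_decision_head,
    set_representation_mode,
)

__all__ = ["TrainConfig", "train_network", "CNNClassifier"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for one training stage."""

    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    patience: int = 10
    seed: int = 0
    class_weight: str | None = "balanced"

    def __post_init__(self):
        if min(self.max_epochs, self.batch_size, self.patience) < 1:
            raise ValueError("max_epochs, batch_size and patience must be >= 1")


def _loss_and_grad(logits, y, sample_w, head):
    """Weighted cross-entropy value and d(loss)/d(logits)."""
    wsum = sample_w.sum()
    if head == "sigmoid":
        z = logits[:, 0]
        p = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        loss = -np.sum(sample_w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        dz = (sample_w * (p - y) / wsum)[:, None]
        return loss / wsum, dz
    zmax = logits.max(axis=1, keepdims=True)
    logsumexp = zmax[:, 0] + np.log(np.exp(logits - zmax).sum(axis=1))
    loss = np.sum(sample_w * (logsumexp - logits[np.arange(len(y)), y]))
    p = np.exp(logits - logsumexp[:, None])
    p[np.arange(len(y)), y] -= 1.0
    return loss / wsum, p * (sample_w / wsum)[:, None]


def train_network(
    state: ModelState,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[ModelState, dict]:
    """Train a model state; returns (best checkpoint, per-epoch history)."""
    arch = state.architecture
    if X_train.shape[1] != arch.input_length:
        raise ValueError(
            f"dataset has {X_train.shape[1]} features but the model expects "
            f"{arch.input_length}"
        )
    present = np.unique(y_train)
    if present.size < 2:
        raise ValueError("training subset must contain at least two classes")

    if config.class_weight == "balanced":
        cw = class_weights(y_train)
        weight_vec = np.array([cw.get(int(c), 1.0) for c in range(arch.n_classes)])
    else:
        weight_vec = np.ones(arch.n_classes)

    work = state.copy()
    rng = np.random.default_rng(config.seed)
    net = Network(work, rng=rng)
    opt = Adam(net, lr=config.learning_rate)

    # cache activations at the frozen-prefix boundary once
    prefix = net.frozen_prefix_end()

    def through_prefix(X):
        if prefix == 0:
            return np.asarray(X, dtype=float)
        h = np.asarray(X, dtype=float)[:, None, :]
        out = []
        for i in range(0, len(h), 256):
            hi = h[i : i + 256]
            for layer in net.layers[:prefix]:
                hi = layer.forward(hi, False)
            out.append(hi)
        return np.concatenate(out)

    Xtr = through_prefix(X_train)
    Xva = through_prefix(X_val)

    def forward_tail(Xb, train):
        if prefix == 0:
            return net.forward(Xb, train=train)
        h = Xb
        for layer in net.layers[prefix:]:
            h = layer.forward(h, train)
        return h

    def val_accuracy():
        preds = []
        for i in range(0, len(Xva), 256):
            logits = forward_tail(Xva[i : i + 256], train=False)
            if arch.head_activation == "sigmoid":
                preds.append((logits[:, 0] > 0).astype(int))
            else:
                preds.append(logits.argmax(axis=1))
        return float(np.mean(np.concatenate(preds) == y_val)) if len(y_val) else 0.0

    history = {"train_loss": [], "train_accuracy": [], "val_loss": [], "val_accuracy": []}
    best_acc = -np.inf
    best_params = None
    stale = 0
    n = len(Xtr)

    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            Xb, yb = Xtr[idx], y_train[idx]
            logits = forward_tail(Xb, train=True)
            loss, dlogits = _loss_and_grad(logits, yb, weight_vec[yb], arch.head_activation)
            net.backward(dlogits, stop=prefix)
            opt.step()
            epoch_loss += loss * len(idx)
            if arch.head_activation == "sigmoid":
                epoch_correct += int(np.sum((logits[:, 0] > 0).astype(int) == yb))
            else:
                epoch_correct += int(np.sum(logits.argmax(axis=1) == yb))
        va = val_accuracy()
        vlogits = forward_tail(Xva, train=False) if len(Xva) else np.zeros((0, 1))
        vloss = (_loss_and_grad(vlogits, y_val, weight_vec[y_val], arch.head_activation)[0]
                 if len(Xva) else 0.0)
        history["train_loss"].append(epoch_loss / n)
        history["train_accuracy"].append(epoch_correct / n)
        history["val_loss"].append(float(vloss))
        history["val_accuracy"].append(va)
        if va > best_acc:
            best_acc = va
            best_params = [None if p is None else {k: v.copy() for k, v in p.items()}
                           for p in work.parameters]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    if best_params is not None:
        work.parameters = best_params
    return work, history


class CNNClassifier(BaseEstimator, ClassifierMixin):
    """1D-CNN spectrum classifier with transfer/cumulative-learning hooks.

    Parameters
    ----------
    architecture : str
        ``variant_lecun`` (4 weight layers), ``variant_lenet`` (5) or
        ``variant_vgg9`` (9).
    representation_mode : str
        ``train_all`` (default), ``fine_tune``, ``freeze_all_conv`` or
        ``freeze_all_conv_but_last``; the freeze modes require
        ``init_state``.
    init_state : ModelState or None
        A previously trained model whose convolutional representation is
        carried over; the decision head is re-initialised for the classes
        seen in ``fit``.
    class_weight : "balanced" or None
        Balanced inverse-frequency loss weighting for imbalanced classes.

    Attributes
    ----------
    classes_ : ndarray — class labels seen in fit.
    model_state_ : ModelState — best checkpoint (highest validation accuracy).
    history_ : dict — per-epoch train/validation loss and accuracy.
    """

    def __init__(
        self,
        architecture: str = "variant_lecun",
        representation_mode: str = "train_all",
        init_state: ModelState | None = None,
        max_epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 1e-4,
        patience: int = 10,
        class_weight: str | None = "balanced",
        validation_fraction: float = 0.25,
        random_state: int = 0,
    ):
        self.architecture = architecture
        self.representation_mode = representation_mode
        self.init_state = init_state
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.class_weight = class_weight
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(self.max_epochs, self.batch_size, self.learning_rate,
                           self.patience, self.random_state, self.class_weight)

    def fit(self, X, y, validation=None):
        """Fit on (X, y); ``validation=(X_val, y_val)`` overrides the
        internal stratified carve-out used for checkpoint selection."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]

        if validation is None:
            from ..binning import stratified_split

            vf = self.validation_fraction
            split = stratified_split(y_idx, (1 - vf, vf / 2, vf / 2),
                                     seed=self.random_state)
            # merge the carved test portion back into validation
            tr = split.train
            va = np.sort(np.concatenate([split.validation, split.test]))
            X_train, y_train = X[tr], y_idx[tr]
            X_val, y_val = X[va], y_idx[va]
        else:
            X_train, y_train = X, y_idx
            Xv, yv = validation
            Xv = np.asarray(Xv, dtype=float)
            lookup = {c: i for i, c in enumerate(self.classes_)}
            y_val = np.array([lookup[v] for v in np.asarray(yv)])
            X_val = Xv

        if self.representation_mode in ("freeze_all_conv", "freeze_all_conv_but_last") \
                and self.init_state is None:
            raise ValueError(f"{self.representation_mode} requires init_state")

        if self.init_state is not None:
            if self.init_state.architecture.input_length != X.shape[1]:
                raise ValueError(
                    f"init_state expects {self.init_state.architecture.input_length} "
                    f"features, data has {X.shape[1]}"
                )
            state = replace_decision_head(self.init_state, n_classes,
                                          seed=self.random_state)
        else:
            arch = build_architecture(self.architecture, X.shape[1], n_classes)
            state = init_parameters(arch, seed=self.random_state)
        state = set_representation_mode(state, self.representation_mode)

        self.model_state_, self.history_ = train_network(
            state, X_train, y_train, X_val, y_val, self._config()
        )
        return self

    def predict_proba(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        net = Network(self.model_state_)
        proba = net.predict_proba(X)
        if self.model_state_.architecture.head_activation == "sigmoid":
            return proba  # already (n, 2)
        return proba

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def _check_fitted(self):
        if not hasattr(self, "model_state_"):
            raise RuntimeError("CNNClassifier is not fitted")
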