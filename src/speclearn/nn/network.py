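"""Runtime network: parameters, forward/backward passes and Adam.

Activations flow as ``(batch, channels, length)`` tensors through the
convolutional stack and as ``(batch, features)`` matrices after the
flatten layer.  Convolutions are "valid" and implemented with
sliding-window views feeding BLAS matmuls.  Weights are He-normal
initialised (sd ``sqrt(2 / fan_in)``, the variance-preserving choice for
rectifier activations); biases start at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architectures import ArchitectureSpec, LayerSpec, layer_output_shapes

__all__ = [
    "ModelState",
    "Network",
    "init_parameters",
    "class_weights",
    "replace_decision_head",
    "set_representation_mode",
    "REPRESENTATION_MODES",
]

REPRESENTATION_MODES = (
    "train_all",
    "fine_tune",
    "freeze_all_conv",
    "freeze_all_conv_but_last",
)


@dataclass
class ModelState:
    """Architecture plus per-layer parameter tensors.

    ``parameters[i]`` is ``None`` for parameterless layers and a
    ``{"W": ..., "b": ...}`` dict for conv/dense/output layers.
    """

    architecture: ArchitectureSpec
    parameters: list[dict | None]
    init_seed: int = 0

    def copy(self) -> "ModelState":
        params = [None if p is None else {k: v.copy() for k, v in p.items()}
                  for p in self.parameters]
        return ModelState(self.architecture.copy(), params, self.init_seed)

    def n_parameters(self) -> int:
        return sum(int(v.size) for p in self.parameters if p for v in p.values())

    def representation_parameters(self) -> list[dict]:
        end = self.architecture.representation_end
        return [p for p in self.parameters[:end] if p is not None]

    def decision_parameters(self) -> list[dict]:
        end = self.architecture.representation_end
        return [p for p in self.parameters[end:] if p is not None]


def _he_normal(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def init_parameters(arch: ArchitectureSpec, seed: int = 0) -> ModelState:
    """He-normal weights, zero biases, reproducible per seed."""
    rng = np.random.default_rng(seed)
    shapes = layer_output_shapes(arch)
    params: list[dict | None] = []
    in_shape: tuple[int, int] | int = (1, arch.input_length)
    for spec, out_shape in zip(arch.layers, shapes, strict=True):
        if spec.kind == "conv1d":
            c_in, _ = in_shape
            fan_in = c_in * spec.kernel_length
            params.append({
                "W": _he_normal(rng, (spec.filters, c_in, spec.kernel_length), fan_in),
                "b": np.zeros(spec.filters),
            })
        elif spec.kind in ("dense", "output"):
            n_in = in_shape if isinstance(in_shape, int) else int(np.prod(in_shape))
            params.append({
                "W": _he_normal(rng, (n_in, spec.units), n_in),
                "b": np.zeros(spec.units),
            })
        else:
            params.append(None)
        in_shape = out_shape
    return ModelState(arch.copy(), params, init_seed=seed)


def class_weights(labels) -> dict[int, float]:
    """Balanced inverse-frequency weights: w_c = n_total / (n_classes * n_c)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 1:
        raise ValueError("every class needs at least one sample")
    n_total, n_classes = labels.size, classes.size
    return {int(c): float(n_total / (n_classes * n_c)) for c, n_c in zip(classes, counts)}


def set_representation_mode(state: ModelState, mode: str) -> ModelState:
    """Return a copy with per-layer trainable flags set for the given mode.

    train_all / fine_tune
        every weight layer trainable (fine_tune differs only in that the
        incoming parameters are a previously trained state);
    freeze_all_conv
        the convolutional representation is frozen, decision layers train;
    freeze_all_conv_but_last
        every conv layer frozen except the final one, decision layers train.
    """
    if mode not in REPRESENTATION_MODES:
        raise ValueError(f"unknown representation mode {mode!r}")
    out = state.copy()
    conv_idx = out.architecture.conv_layer_indices
    for i, spec in enumerate(out.architecture.layers):
        if not spec.has_weights:
            continue
        if mode in ("train_all", "fine_tune"):
            spec.trainable = True
        elif mode == "freeze_all_conv":
            spec.trainable = spec.kind != "conv1d"
        else:  # freeze_all_conv_but_last
            spec.trainable = spec.kind != "conv1d" or i == conv_idx[-1]
    return out


def replace_decision_head(state: ModelState, n_classes: int, seed: int = 0) -> ModelState:
    """New decision layers for a new task; representation kept bitwise.

    Dense and output parameters are re-initialised (He normal) and the
    output head switches between a single sigmoid unit (binary) and an
    ``n_classes``-unit softmax automatically.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    arch = state.architecture.copy()
    arch.n_classes = n_classes
    arch.head_activation = "sigmoid" if n_classes == 2 else "softmax"
    for spec in arch.layers:
        if spec.kind == "output":
            spec.units = 1 if n_classes == 2 else n_classes
    fresh = init_parameters(arch, seed=seed)
    out = fresh
    end = arch.representation_end
    for i in range(end):
        if state.parameters[i] is not None:
            out.parameters[i] = {k: v.copy() for k, v in state.parameters[i].items()}
    out.init_seed = seed
    return out


# ---------------------------------------------------------------- runtime


class _Conv1D:
    def __init__(self, spec: LayerSpec, params: dict):
        self.spec, self.params = spec, params
        self.grads = {k: np.zeros_like(v) for k, v in params.items()}

    def forward(self, x, train):
        # x: (B, C, L) -> windows (B, C, L_out, K)
        K = self.spec.kernel_length
        self._xw = sliding_window_view(x, K, axis=2)
        W = self.params["W"]  # (F, C, K)
        out = np.tensordot(self._xw, W, axes=([1, 3], [1, 2]))  # (B, L_out, F)
        out += self.params["b"]
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, dout):
        # dout: (B, F, L_out)
        W = self.params["W"]
        self.grads["W"][...] = np.einsum("bfl,bclk->fck", dout, self._xw, optimize=True)
        self.grads["b"][...] = dout.sum(axis=(0, 2))
        B, C = self._xw.shape[0], self._xw.shape[1]
        L_out, K = dout.shape[2], self.spec.kernel_length
        dx = np.zeros((B, C, L_out + K - 1))
        for k in range(K):
            dx[:, :, k : k + L_out] += np.einsum("bfl,fc->bcl", dout, W[:, :, k],
                                                 optimize=True)
        self._xw = None
        return dx


class _MaxPool1D:
    def __init__(self, spec: LayerSpec):
        self.spec = spec

    def forward(self, x, train):
        p = self.spec.pool_length
        B, C, L = x.shape
        n = L // p
        xr = x[:, :, : n * p].reshape(B, C, n, p)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, dout):
        p = self.spec.pool_length
        B, C, n = dout.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, :, : n * p].reshape(B, C, n, p)
        bi, ci, ni = np.ogrid[:B, :C, :n]
        dxr[bi, ci, ni, self._arg] = dout
        return dx


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, spec: LayerSpec, params: dict):
        self.spec, self.params = spec, params
        self.grads = {k: np.zeros_like(v) for k, v in params.items()}

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class _LeakyReLU:
    def __init__(self, spec: LayerSpec):
        self.slope = spec.slope

    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class _Dropout:
    def __init__(self, spec: LayerSpec, rng: np.random.Generator):
        self.rate, self.rng = spec.rate, rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Network:
    """Executable network bound to a :class:`ModelState`'s parameter tensors.

    Mutating the network's parameters mutates the state it was built from;
    callers that need isolation copy the state first.
    """

    def __init__(self, state: ModelState, rng: np.random.Generator | None = None):
        self.state = state
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.layers = []
        for spec, params in zip(state.architecture.layers, state.parameters, strict=True):
            if spec.kind == "conv1d":
                self.layers.append(_Conv1D(spec, params))
            elif spec.kind == "maxpool1d":
                self.layers.append(_MaxPool1D(spec))
            elif spec.kind == "flatten":
                self.layers.append(_Flatten())
            elif spec.kind in ("dense", "output"):
                self.layers.append(_Dense(spec, params))
            elif spec.kind == "activation":
                self.layers.append(_LeakyReLU(spec))
            elif spec.kind == "dropout":
                self.layers.append(_Dropout(spec, self.rng))
            else:  # pragma: no cover
                raise ValueError(f"unknown layer kind {spec.kind!r}")

    def forward(self, X, train=False, start=0):
        """Logits for a batch; ``start`` skips an already-computed prefix."""
        if start == 0:
            h = np.asarray(X, dtype=float)[:, None, :]  # (B, 1, L)
        else:
            h = X
        for layer in self.layers[start:]:
            h = layer.forward(h, train)
        return h

    def backward(self, dlogits, stop=0):
        g = dlogits
        for layer in reversed(self.layers[stop:]):
            g = layer.backward(g)
        return g

    def predict_proba(self, X, start=0, batch_size=256):
        arch = self.state.architecture
        outs = []
        for i in range(0, len(X), batch_size):
            logits = self.forward(X[i : i + batch_size], train=False, start=start)
            if arch.head_activation == "sigmoid":
                p = 1.0 / (1.0 + np.exp(-logits[:, 0]))
                outs.append(np.column_stack([1 - p, p]))
            else:
                z = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(z)
                outs.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(outs)

    def trainable_layers(self):
        return [
            l for l, spec in zip(self.layers, self.state.architecture.layers, strict=True)
            if spec.has_weights and spec.trainable
        ]

    def frozen_prefix_end(self) -> int:
        """Longest deterministic all-frozen prefix (for feature caching)."""
        end = 0
        for i, spec in enumerate(self.state.architecture.layers):
            if spec.kind == "dropout":
                break
            if spec.has_weights and spec.trainable:
                break
            end = i + 1
        return end


class Adam:
    """Adam over the trainable parameters of a network."""

    def __init__(self, network: Network, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.slots = []
        for layer in network.trainable_layers():
            for key in layer.params:
                self.slots.append(
                    (layer.params, layer.grads, key,
                     np.zeros_like(layer.params[key]), np.zeros_like(layer.params[key]))
                )

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for params, grads, key, m, v in self.slots:
            g = grads[key]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            params[key] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
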