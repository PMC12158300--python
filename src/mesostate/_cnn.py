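"""Minimal deterministic CNN on 4x4 multi-channel inputs (pure numpy).

Two convolutional layers (2x2 kernels, same padding), two 2x2 max-pool
layers and two fully connected layers, trained with Adam on softmax
cross-entropy.  The inputs here are tiny block tensors, so explicit
kernel-offset loops with einsum contractions are both simple and fast,
and every source of randomness flows from one seeded generator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 2x2 convolution (pad one row/col at bottom/right)."""
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
    out = np.zeros((n, w.shape[0], h, wd))
    for di in range(2):
        for dj in range(2):
            out += np.einsum(
                "nchw,fc->nfhw", xp[:, :, di : di + h, dj : dj + wd], w[:, :, di, dj]
            )
    return out + b[None, :, None, None]


def _conv_backward(x, w, dout):
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (0, 1), (0, 1)))
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for di in range(2):
        for dj in range(2):
            patch = xp[:, :, di : di + h, dj : dj + wd]
            dw[:, :, di, dj] = np.einsum("nfhw,nchw->fc", dout, patch)
            dxp[:, :, di : di + h, dj : dj + wd] += np.einsum(
                "nfhw,fc->nchw", dout, w[:, :, di, dj]
            )
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, :h, :wd], dw, db


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    mask = mask / mask.sum(axis=(3, 5), keepdims=True)  # split ties evenly
    return out, mask


def _pool_backward(mask, dout):
    n, c, h2, _, w2, _ = mask.shape
    dxr = mask * dout[:, :, :, None, :, None]
    return dxr.reshape(n, c, h2 * 2, w2 * 2)


@dataclass
class CNNSpec:
    """Architecture and training hyperparameters.

    The layer structure is fixed (2 conv, 2 pool, 2 fully connected);
    only widths and the optimisation schedule are configurable.
    """

    in_channels: int = 4
    conv_channels: tuple[int, int] = (8, 16)
    hidden: int = 32
    n_classes: int = 2
    learning_rate: float = 5e-3
    epochs: int = 300
    batch_size: int = 64
    patience: int = 30
    weight_decay: float = 1e-4

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "in": self.in_channels,
                "conv": list(self.conv_channels),
                "hidden": self.hidden,
                "classes": self.n_classes,
                "layers": "conv-pool-conv-pool-fc-fc",
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CNNModel:
    spec: CNNSpec
    params: dict[str, np.ndarray]
    history: dict[str, list[float]] = field(default_factory=dict)

    # -- inference -----------------------------------------------------
    def _forward(self, x, cache=False):
        p = self.params
        z1 = _conv_forward(x, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        p1, m1 = _pool_forward(a1)
        z2 = _conv_forward(p1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        p2, m2 = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["w3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        logits = a3 @ p["w4"] + p["b4"]
        if cache:
            return logits, (x, z1, a1, p1, m1, z2, a2, m2, flat, z3, a3)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self._forward(np.asarray(x, dtype=np.float64))
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    # -- serialisation -------------------------------------------------
    def to_jsonable(self) -> dict:
        return {
            "fingerprint": self.spec.fingerprint(),
            "spec": self.spec.__dict__ | {"conv_channels": list(self.spec.conv_channels)},
            "params": {k: v.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "CNNModel":
        spec_dict = dict(obj["spec"])
        spec_dict["conv_channels"] = tuple(spec_dict["conv_channels"])
        spec = CNNSpec(**spec_dict)
        if obj.get("fingerprint") and obj["fingerprint"] != spec.fingerprint():
            raise ValueError("architecture fingerprint mismatch")
        params = {k: np.asarray(v, dtype=np.float64) for k, v in obj["params"].items()}
        return cls(spec=spec, params=params)


def _init_params(spec: CNNSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    c1, c2 = spec.conv_channels

    def he(shape, fan_in):
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    return {
        "w1": he((c1, spec.in_channels, 2, 2), spec.in_channels * 4),
        "b1": np.zeros(c1),
        "w2": he((c2, c1, 2, 2), c1 * 4),
        "b2": np.zeros(c2),
        "w3": he((c2, spec.hidden), c2),
        "b3": np.zeros(spec.hidden),
        "w4": he((spec.hidden, spec.n_classes), spec.hidden),
        "b4": np.zeros(spec.n_classes),
    }


def _loss_and_grads(model: CNNModel, x, y):
    p = model.params
    n = x.shape[0]
    logits, cache = model._forward(x, cache=True)
    (x0, z1, a1, p1, m1, z2, a2, m2, flat, z3, a3) = cache

    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))

    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n

    grads = {}
    grads["w4"] = a3.T @ dlogits
    grads["b4"] = dlogits.sum(axis=0)
    da3 = dlogits @ p["w4"].T
    dz3 = da3 * (z3 > 0)
    grads["w3"] = flat.T @ dz3
    grads["b3"] = dz3.sum(axis=0)
    dflat = dz3 @ p["w3"].T
    dp2 = dflat.reshape(n, -1, 1, 1)
    da2 = _pool_backward(m2, dp2)
    dz2 = da2 * (z2 > 0)
    dp1, grads["w2"], grads["b2"] = _conv_backward(p1, p["w2"], dz2)
    da1 = _pool_backward(m1, dp1)
    dz1 = da1 * (z1 > 0)
    _, grads["w1"], grads["b1"] = _conv_backward(x0, p["w1"], dz1)

    if model.spec.weight_decay:
        for k in ("w1", "w2", "w3", "w4"):
            loss += 0.5 * model.spec.weight_decay * float(np.sum(p[k] ** 2))
            grads[k] = grads[k] + model.spec.weight_decay * p[k]
    return loss, grads


def _eval_loss(model: CNNModel, x, y) -> float:
    probs = model.predict_proba(x)
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300)))


def train_cnn(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    spec: CNNSpec | None = None,
    seed: int = 0,
) -> CNNModel:
    """Train with Adam and early stopping on validation loss."""
    spec = spec or CNNSpec()
    rng = np.random.default_rng(seed)
    x_train = np.asarray(x_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    model = CNNModel(spec=spec, params=_init_params(spec, rng))

    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(val) for k, val in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0

    best_val = np.inf
    best_params = {k: p.copy() for k, p in model.params.items()}
    stale = 0
    history = {"train_loss": [], "val_loss": []}

    n = x_train.shape[0]
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            loss, grads = _loss_and_grads(model, x_train[idx], y_train[idx])
            epoch_loss += loss * len(idx)
            t += 1
            for k in model.params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                model.params[k] -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history["train_loss"].append(epoch_loss / n)

        val_loss = _eval_loss(model, x_val, y_val)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: p.copy() for k, p in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= spec.patience:
                break

    model.params = best_params
    model.history = history
    return model
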