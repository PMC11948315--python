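"""A desk-scale convolutional classifier with swappable activations.

Two 3x3 convolution blocks (same padding, 2x2 mean pooling) feed a linear
softmax head.  Every convolution's nonlinearity is a registered
:class:`~afcs.activations.ActivationSite`, so the active function can be
swapped mid-training without touching a weight; the softmax head is not a
site.  Training uses minibatch Adamax (default step size 1e-3, the
optimizer's standard defaults) on categorical cross-entropy, with inputs
scaled to [0, 1].  Snapshots capture weights, optimizer state, data-order
RNG state, epoch counter and active activation, so ``restore`` is an exact
round-trip and repeated runs from a snapshot are bit-identical.

The model is deliberately small (a few thousand parameters): it exists to
exercise the switching controller end to end on synthetic data, not to
compete on real benchmarks.
"""

from __future__ import annotations

import copy
from typing import Any

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .activations import (
    ActivationSite,
    DEFAULT_CATALOG,
    ActivationCatalog,
    swap_activation,
)
from .evaluation import (
    MetricsReport,
    categorical_crossentropy,
    classification_metrics,
    confusion_matrix,
)

__all__ = ["TinyCNN"]


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, C*9) patches of a same-padded 3x3 window."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
    return win.reshape(n, h, w, c * 9)


def _col2im(dcols: np.ndarray, in_shape) -> np.ndarray:
    """Scatter-add patch gradients back to the (same-padded) input."""
    n, h, w, c = in_shape
    dxp = np.zeros((n, h + 2, w + 2, c))
    d = dcols.reshape(n, h, w, c, 3, 3)
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + h, j : j + w, :] += d[:, :, :, :, i, j]
    return dxp[:, 1:-1, 1:-1, :]


def _pool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def _unpool2(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=1), 2, axis=2) / 4.0


class TinyCNN:
    """TrainerPort-conformant two-block CNN on an in-memory dataset.

    ``data`` maps split names ("train", "val", "test") to ``(images,
    labels)`` pairs; images are (N, H, W, 3) rasters in [0, 255], H and W
    divisible by 4.
    """

    def __init__(
        self,
        data: dict[str, tuple[np.ndarray, np.ndarray]],
        n_classes: int,
        seed: int = 0,
        activation: str = "ReLU",
        filters: tuple[int, int] = (8, 16),
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        catalog: ActivationCatalog | None = None,
    ):
        if n_classes < 2:
            raise ValueError("need at least two classes")
        self.catalog = DEFAULT_CATALOG if catalog is None else catalog
        self.n_classes = n_classes
        self.batch_size = batch_size
        self.lr = learning_rate
        self._data = {
            name: (np.asarray(x, dtype=float) / 255.0, np.asarray(y, dtype=int))
            for name, (x, y) in data.items()
        }
        if "train" not in self._data or "val" not in self._data:
            raise ValueError("data must provide 'train' and 'val' splits")
        h, w = self._data["train"][0].shape[1:3]
        if h % 4 or w % 4:
            raise ValueError("image height/width must be divisible by 4")
        f1, f2 = filters
        n_feat = (h // 4) * (w // 4) * f2
        self._rng = np.random.default_rng(seed)
        self.params = {
            "W1": _he_init(self._rng, (3 * 9, f1), 3 * 9),
            "b1": np.zeros(f1),
            "W2": _he_init(self._rng, (f1 * 9, f2), f1 * 9),
            "b2": np.zeros(f2),
            "W3": _he_init(self._rng, (n_feat, n_classes), n_feat),
            "b3": np.zeros(n_classes),
        }
        self._m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._u = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._t = 0
        spec = self.catalog[activation]
        self.activation_sites = [
            ActivationSite("block1", spec),
            ActivationSite("block2", spec),
        ]
        self._epoch = 0
        self._snapshots: dict[int, dict] = {}
        self._next_token = 0
        self.last_epoch_metrics: dict[str, float] = {}

    # -- TrainerPort surface ------------------------------------------------

    @property
    def current_epoch(self) -> int:
        return self._epoch

    @property
    def active_activation(self) -> str:
        return self.activation_sites[0].name

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def parameter_checksum(self) -> bytes:
        import hashlib

        digest = hashlib.sha256()
        for key in sorted(self.params):
            digest.update(np.ascontiguousarray(self.params[key]).tobytes())
        return digest.digest()

    def set_activation(self, name: str) -> None:
        swap_activation(self, name, self.catalog)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def snapshot(self) -> int:
        token = self._next_token
        self._next_token += 1
        self._snapshots[token] = {
            "params": {k: v.copy() for k, v in self.params.items()},
            "m": {k: v.copy() for k, v in self._m.items()},
            "u": {k: v.copy() for k, v in self._u.items()},
            "t": self._t,
            "epoch": self._epoch,
            "rng": copy.deepcopy(self._rng.bit_generator.state),
            "activation": self.active_activation,
        }
        return token

    def restore(self, token: int) -> None:
        snap = self._snapshots[token]
        self.params = {k: v.copy() for k, v in snap["params"].items()}
        self._m = {k: v.copy() for k, v in snap["m"].items()}
        self._u = {k: v.copy() for k, v in snap["u"].items()}
        self._t = snap["t"]
        self._epoch = snap["epoch"]
        self._rng.bit_generator.state = copy.deepcopy(snap["rng"])
        self.set_activation(snap["activation"])

    def train_one_epoch(self) -> float:
        x, y = self._data["train"]
        order = self._rng.permutation(len(y))
        batch_losses = []
        for start in range(0, len(y), self.batch_size):
            idx = order[start : start + self.batch_size]
            batch_losses.append(self._train_batch(x[idx], y[idx]))
        val_loss, val_acc = self._loss_and_accuracy("val")
        self._epoch += 1
        self.last_epoch_metrics = {
            "train_loss": float(np.mean(batch_losses)),
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        }
        return val_loss

    def evaluate(self, split: str = "test") -> MetricsReport:
        x, y = self._data[split]
        probs = self._forward(x)[-1]
        cm = confusion_matrix(y, probs.argmax(axis=1), self.n_classes)
        report = classification_metrics(cm, averaging="weighted")
        loss = categorical_crossentropy(probs, y)
        return MetricsReport(
            accuracy=report.accuracy,
            precision=report.precision,
            recall=report.recall,
            f1=report.f1,
            loss=loss,
            averaging=report.averaging,
        )

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(images, dtype=float) / 255.0)[-1]

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray):
        p = self.params
        s1, s2 = self.activation_sites
        cols1 = _im2col(x)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = s1.forward(z1)
        h1 = _pool2(a1)
        cols2 = _im2col(h1)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = s2.forward(z2)
        h2 = _pool2(a2)
        flat = h2.reshape(len(x), -1)
        logits = flat @ p["W3"] + p["b3"]
        logits = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        return x, cols1, z1, h1, cols2, z2, h2, flat, probs

    def _train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        p = self.params
        s1, s2 = self.activation_sites
        xin, cols1, z1, h1, cols2, z2, h2, flat, probs = self._forward(x)
        n = len(y)
        loss = categorical_crossentropy(probs, y)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads = {
            "W3": flat.T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["W3"].T
        dh2 = dflat.reshape(h2.shape)
        da2 = _unpool2(dh2)
        dz2 = da2 * s2.backward(z2)
        dz2_flat = dz2.reshape(-1, dz2.shape[-1])
        grads["W2"] = cols2.reshape(-1, cols2.shape[-1]).T @ dz2_flat
        grads["b2"] = dz2_flat.sum(axis=0)
        dcols2 = dz2_flat @ p["W2"].T
        dh1 = _col2im(dcols2.reshape(cols2.shape), h1.shape)
        da1 = _unpool2(dh1)
        dz1 = da1 * s1.backward(z1)
        dz1_flat = dz1.reshape(-1, dz1.shape[-1])
        grads["W1"] = cols1.reshape(-1, cols1.shape[-1]).T @ dz1_flat
        grads["b1"] = dz1_flat.sum(axis=0)
        self._adamax_update(grads)
        return loss

    def _adamax_update(self, grads, beta1=0.9, beta2=0.999, eps=1e-7):
        self._t += 1
        correction = 1.0 - beta1**self._t
        for key, g in grads.items():
            self._m[key] = beta1 * self._m[key] + (1.0 - beta1) * g
            self._u[key] = np.maximum(beta2 * self._u[key], np.abs(g))
            self.params[key] -= (self.lr / correction) * self._m[key] / (
                self._u[key] + eps
            )

    def _loss_and_accuracy(self, split: str) -> tuple[float, float]:
        x, y = self._data[split]
        probs = self._forward(x)[-1]
        loss = categorical_crossentropy(probs, y)
        acc = float((probs.argmax(axis=1) == y).mean())
        return loss, acc
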