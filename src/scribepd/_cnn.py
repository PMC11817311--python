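"""Compact convolutional network used by the image branch.

Architecture: three 5×5 same-padded convolutions with 16, 8 and 4
filters, each followed by ReLU and a 2×2 max-pool that halves the
feature maps, then fully connected layers of 512, 64 and 2 units (ReLU,
ReLU, softmax).  For 144×216 inputs the conv stack ends at 18×27×4, so
the flattened embedding has 1944 dimensions.

Everything runs in float32 numpy: im2col convolutions, deterministic He
initialization from a seed, Adam updates, and per-layer trainability
flags that implement the freezing schemes (only layers listed as
trainable are updated; frozen weights are bit-identical afterwards).
Training is deterministic for a fixed seed in single-threaded use.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

CONV_LAYERS = ("conv1", "conv2", "conv3")
HEAD_LAYERS = ("fc1", "fc2", "fc3")

#: Convolutional layers fine-tuned under each freezing scheme (the
#: classifier head is always trainable during fine-tuning).
FREEZING_SCHEMES: dict[str, tuple[str, ...]] = {
    "fully_frozen": (),
    "partially_frozen": ("conv1",),
    "semi_frozen": ("conv1", "conv2"),
    "unfrozen": ("conv1", "conv2", "conv3"),
}


def _he(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


class _Layer:
    W: np.ndarray
    b: np.ndarray

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def n_params(self) -> int:
        return self.W.size + self.b.size


class _Conv(_Layer):
    """5×5 same-padded convolution via im2col."""

    def __init__(self, rng, cin: int, cout: int, k: int = 5):
        self.cin, self.cout, self.k = cin, cout, k
        self.W = _he(rng, cin * k * k, (cout, cin * k * k))
        self.b = np.zeros(cout, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n, h * w, c * self.k * self.k)
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, (n, c, h, w))
        return out.transpose(0, 2, 1).reshape(n, self.cout, h, w)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        cols, (n, c, h, w) = self._cache
        self._cache = None
        d2 = dout.reshape(n, self.cout, h * w).transpose(0, 2, 1)
        dW = np.einsum("npk,npf->fk", cols, d2, optimize=True)
        db = d2.sum(axis=(0, 1))
        dcols = (d2 @ self.W).reshape(n, h, w, c, self.k, self.k)
        pad = self.k // 2
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2)
        return dxp[:, :, pad:pad + h, pad:pad + w], [dW, db]


class _Dense(_Layer):
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = _he(rng, n_in, (n_out, n_in))
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        x = self._cache
        self._cache = None
        return dout @ self.W, [dout.T @ x, dout.sum(axis=0)]


def _relu_forward(x, train):
    out = np.maximum(x, 0.0)
    return out, (x > 0) if train else None


def _maxpool_forward(x, train):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape) if train else None


def _maxpool_backward(dout, cache):
    idx, (n, c, h, w) = cache
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx).reshape(n, c, h, w)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    patience: int = 3          # early stopping on held-out loss
    seed: int = 0


class ConvNet:
    """The 3-conv / 3-dense network with per-layer freezing."""

    def __init__(self, input_hw: tuple[int, int] = (144, 216),
                 filters: tuple[int, int, int] = (16, 8, 4),
                 fc_sizes: tuple[int, int, int] = (512, 64, 2),
                 seed: int = 0):
        self.input_hw = input_hw
        self.filters = filters
        self.fc_sizes = fc_sizes
        self.seed = seed
        rng = np.random.default_rng(seed)
        h, w = input_hw
        self.layers: dict[str, _Layer] = {}
        cin = 1
        for name, cout in zip(CONV_LAYERS, filters):
            self.layers[name] = _Conv(rng, cin, cout)
            cin = cout
            h, w = h // 2, w // 2
        self.embed_dim = h * w * filters[-1]
        n_in = self.embed_dim
        for name, n_out in zip(HEAD_LAYERS, fc_sizes):
            self.layers[name] = _Dense(rng, n_in, n_out)
            n_in = n_out
        self._adam_state: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        self._adam_t = 0

    # -- forward ----------------------------------------------------------

    def _conv_stack(self, x: np.ndarray, train: bool):
        caches = []
        for name in CONV_LAYERS:
            x = self.layers[name].forward(x, train)
            x, rc = _relu_forward(x, train)
            x, pc = _maxpool_forward(x, train)
            caches.append((name, rc, pc))
        return x, caches

    def embed(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Flattened last conv feature map per image, shape (n, embed_dim)."""
        x = self._as_input(images)
        out = []
        for i in range(0, len(x), batch_size):
            fmap, _ = self._conv_stack(x[i:i + batch_size], train=False)
            out.append(fmap.reshape(len(fmap), -1))
        return np.concatenate(out, axis=0).astype(np.float64)

    def predict_proba(self, images: np.ndarray, batch_size: int = 16) -> np.ndarray:
        x = self._as_input(images)
        probs = []
        for i in range(0, len(x), batch_size):
            fmap, _ = self._conv_stack(x[i:i + batch_size], train=False)
            a = fmap.reshape(len(fmap), -1)
            for name in HEAD_LAYERS:
                a = self.layers[name].forward(a, train=False)
                if name != HEAD_LAYERS[-1]:
                    a, _ = _relu_forward(a, False)
            probs.append(softmax(a))
        return np.concatenate(probs, axis=0)

    @staticmethod
    def _as_input(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        return x

    # -- training ---------------------------------------------------------

    def _forward_backward(self, xb: np.ndarray, yb: np.ndarray,
                          trainable: set[str]) -> tuple[float, dict[str, list]]:
        fmap, conv_caches = self._conv_stack(xb, train=True)
        a = fmap.reshape(len(fmap), -1)
        head_caches = []
        for name in HEAD_LAYERS:
            a = self.layers[name].forward(a, train=True)
            if name != HEAD_LAYERS[-1]:
                a, rc = _relu_forward(a, True)
                head_caches.append((name, rc))
        probs = softmax(a)
        n = len(xb)
        loss = float(-np.mean(np.log(probs[np.arange(n), yb] + 1e-12)))

        grads: dict[str, list] = {}
        d = (probs - np.eye(probs.shape[1], dtype=np.float32)[yb]) / n
        d = d.astype(np.float32)
        for name in reversed(HEAD_LAYERS):
            if name != HEAD_LAYERS[-1]:
                hn, rc = head_caches.pop()
                d = d * rc
            d, g = self.layers[name].backward(d)
            grads[name] = g
        # Freezing schemes unfreeze convolutions from conv1 upward, so when
        # any conv layer is trainable the gradient must traverse them all;
        # when none is, the conv backward pass is skipped entirely.
        if any(name in trainable for name in CONV_LAYERS):
            d = d.reshape(fmap.shape).astype(np.float32)
            for name, rc, pc in reversed(conv_caches):
                d = _maxpool_backward(d, pc)
                d = d * rc
                d, g = self.layers[name].backward(d)
                grads[name] = g
        return loss, grads

    def _adam_step(self, grads: dict[str, list], trainable: set[str],
                   lr: float, beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for name in trainable:
            if name not in grads:
                continue
            layer = self.layers[name]
            if name not in self._adam_state:
                self._adam_state[name] = [
                    (np.zeros_like(p), np.zeros_like(p)) for p in layer.params()]
            for p, g, (m, v) in zip(layer.params(), grads[name],
                                    self._adam_state[name]):
                g = g.astype(np.float32)
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, images: np.ndarray, labels: np.ndarray,
            config: "TrainConfig | None" = None,
            val_images: "np.ndarray | None" = None,
            val_labels: "np.ndarray | None" = None,
            trainable: "set[str] | None" = None) -> list[float]:
        """Minimize softmax cross-entropy with Adam; returns epoch losses.

        Only layers in ``trainable`` (default: all) are updated.  With
        validation data, training stops early when held-out loss fails
        to improve for ``patience`` epochs and the best weights are
        restored.
        """
        cfg = config or TrainConfig()
        x = self._as_input(images)
        y = np.asarray(labels, dtype=int)
        if trainable is None:
            trainable = set(CONV_LAYERS) | set(HEAD_LAYERS)
        rng = np.random.default_rng(cfg.seed)
        self._adam_state = {}
        self._adam_t = 0
        history: list[float] = []
        best_val = np.inf
        best_weights = None
        stall = 0
        for _epoch in range(cfg.epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                loss, grads = self._forward_backward(x[idx], y[idx], trainable)
                self._adam_step(grads, trainable, cfg.lr)
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if val_images is not None:
                vp = self.predict_proba(val_images)
                vy = np.asarray(val_labels, dtype=int)
                vloss = float(-np.mean(np.log(vp[np.arange(len(vy)), vy] + 1e-12)))
                if vloss < best_val - 1e-5:
                    best_val = vloss
                    best_weights = self.get_weights()
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if best_weights is not None:
            self.set_weights(best_weights)
        return history

    # -- bookkeeping ------------------------------------------------------

    def get_weights(self) -> dict[str, list[np.ndarray]]:
        return {name: [p.copy() for p in layer.params()]
                for name, layer in self.layers.items()}

    def set_weights(self, weights: dict[str, list[np.ndarray]]) -> None:
        for name, params in weights.items():
            layer = self.layers[name]
            layer.W = params[0].copy()
            layer.b = params[1].copy()

    def clone(self) -> "ConvNet":
        other = ConvNet(self.input_hw, self.filters, self.fc_sizes, self.seed)
        other.set_weights(self.get_weights())
        return other

    def weight_hash(self, layer: str) -> str:
        h = hashlib.sha256()
        for p in self.layers[layer].params():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def layer_param_count(self, layer: str) -> int:
        return self.layers[layer].n_params()

    def trainable_parameter_count(self, scheme: str) -> int:
        """Parameters updated while fine-tuning under a freezing scheme."""
        if scheme not in FREEZING_SCHEMES:
            raise ValueError(f"unknown freezing scheme: {scheme!r}")
        names = FREEZING_SCHEMES[scheme] + HEAD_LAYERS
        return sum(self.layer_param_count(n) for n in names)
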