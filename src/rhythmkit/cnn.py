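"""A compact 2-D convolutional binary classifier for small grayscale images.

Architecture (``small_cnn``): two conv blocks (3×3 conv → ReLU → 2×2 max
pool) followed by a dense logit head, trained with Adam on the binary
cross-entropy.  Sized for 30×30 single-channel inputs, where a deeper
backbone adds nothing; weights are He-initialized from a seeded generator so
training is deterministic up to floating-point ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rhythmkit.errors import ConfigurationError, ValidationError


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, pad: int) -> np.ndarray:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout."""
    n, c, h, wd = x.shape
    f, c2, k, _ = w.shape
    assert c == c2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (n, c, ho, wo, k, k) · (f, c, k, k) → (n, ho, wo, f)
    out = np.tensordot(sw, w, axes=([1, 4, 5], [1, 2, 3]))
    if b is not None:
        out += b
    return np.ascontiguousarray(out.transpose(0, 3, 1, 2))


def _conv2d_grads(
    x: np.ndarray, w: np.ndarray, dout: np.ndarray, pad: int, need_dx: bool = True
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients of a stride-1 conv wrt input, weights, bias."""
    n, c, h, wd = x.shape
    f, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # (n, c, ho, wo, k, k) · (n, f, ho, wo) → (c, k, k, f)
    dw = np.tensordot(sw, dout, axes=([0, 2, 3], [0, 2, 3]))
    dw = dw.transpose(3, 0, 1, 2)
    db = dout.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        # dX: full conv of dout with 180°-rotated, channel-transposed kernels
        w_rot = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx = _conv2d(dout, w_rot, None, pad=k - 1 - pad)
    return dx, dw, db


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2×2/stride-2 max pool (odd trailing rows/cols dropped)."""
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
    flat = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _maxpool2_back(dout: np.ndarray, arg: np.ndarray, in_shape) -> np.ndarray:
    n, c, h, w = in_shape
    h2, w2 = h // 2, w // 2
    flat = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(flat, arg[..., None], dout[..., None], axis=-1)
    dx = np.zeros(in_shape, dtype=dout.dtype)
    dx[:, :, : h2 * 2, : w2 * 2] = (
        flat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h2 * 2, w2 * 2)
    )
    return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SmallCnn:
    """Two conv blocks + dense head; binary classifier on (N, H, W) images."""

    image_side: int = 30
    n_filters: tuple[int, int] = (8, 16)
    seed: int = 0
    epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    params: dict = field(default_factory=dict, repr=False)

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        f1, f2 = self.n_filters
        side = self.image_side // 2 // 2
        d = f2 * side * side
        he = lambda fan, shape: rng.normal(0.0, np.sqrt(2.0 / fan), shape)
        self.params = {
            "w1": he(9, (f1, 1, 3, 3)),
            "b1": np.zeros(f1),
            "w2": he(f1 * 9, (f2, f1, 3, 3)),
            "b2": np.zeros(f2),
            "w3": he(d, (d, 1)),
            "b3": np.zeros(1),
        }

    # forward with cache ---------------------------------------------------
    def _forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        a1 = _conv2d(x, p["w1"], p["b1"], pad=1)
        r1 = np.maximum(a1, 0.0)
        p1, arg1 = _maxpool2(r1)
        a2 = _conv2d(p1, p["w2"], p["b2"], pad=1)
        r2 = np.maximum(a2, 0.0)
        p2, arg2 = _maxpool2(r2)
        flat = p2.reshape(x.shape[0], -1)
        logits = (flat @ p["w3"] + p["b3"]).ravel()
        if not cache:
            return logits
        return logits, (x, a1, r1, p1, arg1, a2, r2, p2, arg2, flat)

    def _backward(self, dlogits: np.ndarray, cache):
        p = self.params
        x, a1, r1, p1, arg1, a2, r2, p2, arg2, flat = cache
        g = {}
        g["w3"] = flat.T @ dlogits[:, None]
        g["b3"] = np.array([dlogits.sum()])
        dflat = dlogits[:, None] @ p["w3"].T
        dp2 = dflat.reshape(p2.shape)
        dr2 = _maxpool2_back(dp2, arg2, r2.shape)
        da2 = dr2 * (a2 > 0)
        dp1, g["w2"], g["b2"] = _conv2d_grads(p1, p["w2"], da2, pad=1)
        dr1 = _maxpool2_back(dp1, arg1, r1.shape)
        da1 = dr1 * (a1 > 0)
        _, g["w1"], g["b1"] = _conv2d_grads(x, p["w1"], da1, pad=1, need_dx=False)
        return g

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy with logits and its parameter grads."""
        logits, cache = self._forward(x, cache=True)
        prob = _sigmoid(logits)
        eps = 1e-12
        loss = -np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps))
        dlogits = (prob - y) / y.size
        return float(loss), self._backward(dlogits, cache)

    def fit(self, images: np.ndarray, labels: np.ndarray) -> "SmallCnn":
        x = np.asarray(images, dtype=float)
        y = np.asarray(labels, dtype=float)
        if x.ndim != 3 or x.shape[1] != self.image_side or x.shape[2] != self.image_side:
            raise ValidationError(
                f"expected (n, {self.image_side}, {self.image_side}) images"
            )
        classes = np.unique(y)
        if classes.size < 2:
            raise ValidationError("stage-2 training needs both classes present")
        frac = y.mean()
        if min(frac, 1 - frac) < 0.01:
            import warnings

            warnings.warn("stage-2 class imbalance exceeds 99:1", stacklevel=2)
        x = x[:, None, :, :]
        self._init_params()
        rng = np.random.default_rng(self.seed + 1)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v2 = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = x.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                _, g = self.loss_and_grads(x[idx], y[idx])
                step += 1
                for k in self.params:
                    gk = g[k] + self.weight_decay * self.params[k]
                    m[k] = b1 * m[k] + (1 - b1) * gk
                    v2[k] = b2 * v2[k] + (1 - b2) * gk * gk
                    mh = m[k] / (1 - b1**step)
                    vh = v2[k] / (1 - b2**step)
                    self.params[k] -= self.learning_rate * mh / (np.sqrt(vh) + eps)
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        if not self.params:
            raise ConfigurationError("model is not trained")
        x = np.asarray(images, dtype=float)[:, None, :, :]
        out = np.empty(x.shape[0])
        for lo in range(0, x.shape[0], 256):
            out[lo : lo + 256] = _sigmoid(self._forward(x[lo : lo + 256]))
        return out

    def predict(self, images: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(images) >= threshold).astype(int)

    # serialization --------------------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            meta=np.array(
                [self.image_side, self.n_filters[0], self.n_filters[1], self.seed]
            ),
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "SmallCnn":
        with np.load(path) as data:
            meta = data["meta"]
            model = cls(
                image_side=int(meta[0]),
                n_filters=(int(meta[1]), int(meta[2])),
                seed=int(meta[3]),
            )
            model.params = {
                k: data[k] for k in ("w1", "b1", "w2", "b2", "w3", "b3")
            }
        return model
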