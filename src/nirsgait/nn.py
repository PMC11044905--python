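"""A small, dependency-free convolutional classifier.

This is the compact trainable model used throughout the package for
desk-scale experiments: three stages (fixed 8x average-pool stem, two 3x3
convolution blocks with ReLU and 2x average pooling, global average pooling
and a linear head), trained with softmax cross-entropy and Adam. Forward
and backward passes are plain numpy; everything is seeded and runs
identically across repeats on the same machine.

The class-mean structure of the encoded fNIRS images (condition-specific
HbO2 shifts, the zero-padding boundary encoding completion time) is well
within its capacity, which keeps cross-validation runs fast.
"""

from __future__ import annotations

import numpy as np


def _im2col3(x: np.ndarray) -> np.ndarray:
    """[B,C,H,W] -> [B, C*9, H*W] of 3x3 same-padded patches."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: [B, C, H, W, 3, 3] -> [B, C, 3, 3, H*W] -> [B, C*9, H*W]
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * 9, h * w)


def _col2im3(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    b, c, h, w = shape
    d = dcols.reshape(b, c, 3, 3, h, w)
    out = np.zeros((b, c, h + 2, w + 2))
    for i in range(3):
        for j in range(3):
            out[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return out[:, :, 1 : 1 + h, 1 : 1 + w]


def _avgpool2(x: np.ndarray) -> np.ndarray:
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=2), 2, axis=3) / 4.0


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean loss and gradient wrt logits for integer labels ``y``."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class ToyCNN:
    """3-block convolutional classifier on 3 x 224 x 224 inputs.

    Parameters
    ----------
    n_classes : output dimensionality of the linear head.
    channels : feature maps of the two convolution blocks.
    covariate_fusion : when True, two standardized covariates (gender,
        cognitive score) are concatenated to the penultimate feature vector
        before the head.
    pooled : spatial size after the fixed average-pool stem; the input
        height/width must be a multiple of it.
    """

    architecture = "toy_cnn"

    def __init__(
        self,
        n_classes: int = 3,
        in_channels: int = 3,
        channels: tuple[int, int] = (8, 16),
        covariate_fusion: bool = False,
        pooled: int = 28,
        seed: int = 0,
    ):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_classes = n_classes
        self.in_channels = in_channels
        self.channels = channels
        self.covariate_fusion = covariate_fusion
        self.pooled = pooled
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        n_feat = c2 + (2 if covariate_fusion else 0)
        he = lambda fan_in, shape: rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)
        self.params = {
            "W1": he(in_channels * 9, (c1, in_channels * 9)),
            "b1": np.zeros(c1),
            "W2": he(c1 * 9, (c2, c1 * 9)),
            "b2": np.zeros(c2),
            "W3": he(n_feat, (n_feat, n_classes)),
            "b3": np.zeros(n_classes),
        }

    # -- plumbing ----------------------------------------------------------

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def get_weights(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict) -> None:
        self.params = {k: v.copy() for k, v in weights.items()}

    def _stem(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        f = h // self.pooled
        if f * self.pooled != h or w // self.pooled * self.pooled != w:
            raise ValueError(f"input size {h}x{w} not a multiple of pooled size {self.pooled}")
        if f == 1:
            return x.astype(float)
        return x.reshape(b, c, self.pooled, f, self.pooled, w // self.pooled).mean(axis=(3, 5))

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, covariates: np.ndarray | None = None):
        p = self.params
        xs = self._stem(np.asarray(x, dtype=float))
        b = xs.shape[0]
        s = self.pooled
        cols1 = _im2col3(xs)
        z1 = (p["W1"] @ cols1 + p["b1"][:, None]).reshape(b, -1, s, s)
        a1 = np.maximum(z1, 0.0)
        h1 = _avgpool2(a1)  # [B, c1, s/2, s/2]
        cols2 = _im2col3(h1)
        z2 = (p["W2"] @ cols2 + p["b2"][:, None]).reshape(b, -1, s // 2, s // 2)
        a2 = np.maximum(z2, 0.0)
        h2 = _avgpool2(a2)  # [B, c2, s/4, s/4]
        feat = h2.mean(axis=(2, 3))  # global average pool
        if self.covariate_fusion:
            if covariates is None:
                raise ValueError("covariate_fusion model requires covariates")
            feat = np.concatenate([feat, np.asarray(covariates, dtype=float)], axis=1)
        logits = feat @ p["W3"] + p["b3"]
        cache = (xs, cols1, z1, h1, cols2, z2, h2, feat)
        return logits, cache

    def backward(self, cache, dlogits: np.ndarray) -> dict:
        p = self.params
        xs, cols1, z1, h1, cols2, z2, h2, feat = cache
        b = xs.shape[0]
        s = self.pooled
        grads = {
            "W3": feat.T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ p["W3"].T
        c2 = h2.shape[1]
        dfeat_conv = dfeat[:, :c2]  # fused covariates receive no gradient path
        dh2 = np.broadcast_to(
            dfeat_conv[:, :, None, None] / (h2.shape[2] * h2.shape[3]), h2.shape
        )
        da2 = _avgpool2_back(dh2)
        dz2 = da2 * (z2 > 0)
        dz2f = dz2.reshape(b, dz2.shape[1], -1)
        grads["W2"] = np.einsum("bif,bjf->ij", dz2f, cols2)
        grads["b2"] = dz2f.sum(axis=(0, 2))
        dcols2 = np.einsum("ij,bif->bjf", p["W2"], dz2f)
        dh1 = _col2im3(dcols2, h1.shape)
        da1 = _avgpool2_back(dh1)
        dz1 = da1 * (z1 > 0)
        dz1f = dz1.reshape(b, dz1.shape[1], -1)
        grads["W1"] = np.einsum("bif,bjf->ij", dz1f, cols1)
        grads["b1"] = dz1f.sum(axis=(0, 2))
        return grads

    def predict_logits(self, x: np.ndarray, covariates: np.ndarray | None = None,
                       batch_size: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            cov = covariates[i : i + batch_size] if covariates is not None else None
            outs.append(self.forward(x[i : i + batch_size], cov)[0])
        return np.concatenate(outs) if outs else np.empty((0, self.n_classes))

    def predict(self, x: np.ndarray, covariates: np.ndarray | None = None) -> np.ndarray:
        return self.predict_logits(x, covariates).argmax(axis=1)


class Adam:
    """Standard Adam update (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
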