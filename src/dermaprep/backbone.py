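"""Reference convolutional backbone for tests and CPU-only runs.

The classification scaffolding is written against a small backbone
contract: ``forward`` maps an image batch to sigmoid class scores while
exposing the final convolutional feature maps, and the gradient of the
class score with respect to those maps is available for Grad-CAM. Any
network with a final conv stack satisfies it; this module ships a small
three-block CNN implemented directly in numpy (im2col convolutions,
hand-written backward pass) so the full train/evaluate/explain loop runs
on one CPU with no deep-learning framework.

Architecture (working resolution 32x32, RGB):
    conv 3->8 (3x3, pad 1) + ReLU + maxpool 2   -> 8 @ 16x16
    conv 8->16 (3x3, pad 1) + ReLU + maxpool 2  -> 16 @ 8x8
    conv 16->16 (3x3, pad 1) + ReLU             -> final maps A, 16 @ 8x8
    global average pool -> dropout -> linear -> logit -> sigmoid
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
from skimage import transform

__all__ = ["BackboneContract", "TinyCNN", "Adam"]


class BackboneContract(Protocol):
    """Duck-typed contract the classify/explain modules rely on."""

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (sigmoid scores in [0,1], pre-sigmoid logits)."""
        ...

    def feature_maps_and_gradient(
        self, image: np.ndarray, class_index: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (A, dScore/dA), both shaped (K, h, w)."""
        ...


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patches for 'same' convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w).transpose(0, 2, 1)


def _col2im(dcols: np.ndarray, shape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dc = dcols.transpose(0, 2, 1).reshape(n, c, k * k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += dc[:, :, i * k + j]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = _im2col(x)
        out = cols @ self.W.T + self.b
        n, hw, c_out = out.shape
        h = w = int(np.sqrt(hw))
        self.cache = (x.shape, cols)
        return out.transpose(0, 2, 1).reshape(n, c_out, h, w)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x_shape, cols = self.cache
        n, c_out, h, w = dout.shape
        d2 = dout.reshape(n, c_out, h * w).transpose(0, 2, 1)
        dW = np.einsum("npo,npf->of", d2, cols)
        db = d2.sum(axis=(0, 1))
        dcols = d2 @ self.W
        return _col2im(dcols, x_shape), dW, db


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    return out, mask


def _maxpool_back(dout: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n, c, h2, _, w2, _ = mask.shape
    d = mask * dout[:, :, :, None, :, None]
    # split gradient evenly among ties (rare with float activations)
    counts = mask.sum(axis=(3, 5), keepdims=True)
    d = d / counts
    return d.reshape(n, c, h2 * 2, w2 * 2)


class TinyCNN:
    """Small reference CNN satisfying :class:`BackboneContract`."""

    def __init__(self, seed: int = 42, input_size: int = 32, dropout: float = 0.5):
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.dropout = dropout
        self.conv1 = _Conv(3, 8, rng)
        self.conv2 = _Conv(8, 16, rng)
        self.conv3 = _Conv(16, 16, rng)
        self.fc_W = rng.normal(0.0, np.sqrt(2.0 / 16), size=16)
        self.fc_b = 0.0
        self._cache: dict | None = None

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        return {
            "c1W": self.conv1.W, "c1b": self.conv1.b,
            "c2W": self.conv2.W, "c2b": self.conv2.b,
            "c3W": self.conv3.W, "c3b": self.conv3.b,
            "fcW": self.fc_W,
        }

    def get_state(self) -> dict:
        state = {k: v.copy() for k, v in self.parameters().items()}
        state["fcb"] = float(self.fc_b)
        return state

    def set_state(self, state: dict) -> None:
        self.conv1.W[:] = state["c1W"]; self.conv1.b[:] = state["c1b"]
        self.conv2.W[:] = state["c2W"]; self.conv2.b[:] = state["c2b"]
        self.conv3.W[:] = state["c3W"]; self.conv3.b[:] = state["c3b"]
        self.fc_W[:] = state["fcW"]; self.fc_b = float(state["fcb"])

    # -- data plumbing ------------------------------------------------------
    def prepare(self, images: np.ndarray | list) -> np.ndarray:
        """uint8 (N, H, W, 3) or list of frames -> float (N, 3, s, s)."""
        if isinstance(images, list):
            images = np.stack(images)
        s = self.input_size
        if images.ndim == 4 and images.shape[1] == 3 and images.shape[2] == s:
            return images.astype(np.float64, copy=False)  # already prepared
        if images.ndim == 3:
            images = images[None]
        out = np.empty((images.shape[0], 3, s, s))
        for i, img in enumerate(images):
            if img.shape[:2] != (s, s):
                img = transform.resize(
                    img.astype(np.float64) / 255.0, (s, s), order=1,
                    mode="edge", anti_aliasing=True, preserve_range=True,
                )
            else:
                img = img.astype(np.float64) / 255.0
            out[i] = img.transpose(2, 0, 1)
        return out

    # -- forward / backward -------------------------------------------------
    def forward(
        self,
        images: np.ndarray | list,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        x = self.prepare(images)
        z1 = self.conv1.forward(x)
        a1 = np.maximum(z1, 0.0)
        p1, m1 = _maxpool(a1)
        z2 = self.conv2.forward(p1)
        a2 = np.maximum(z2, 0.0)
        p2, m2 = _maxpool(a2)
        z3 = self.conv3.forward(p2)
        a3 = np.maximum(z3, 0.0)  # final conv feature maps
        gap = a3.mean(axis=(2, 3))
        if train and self.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            keep = (rng.uniform(size=gap.shape) >= self.dropout) / (1 - self.dropout)
        else:
            keep = np.ones_like(gap)
        dropped = gap * keep
        logits = dropped @ self.fc_W + self.fc_b
        probs = 1.0 / (1.0 + np.exp(-logits))
        self._cache = {
            "z1": z1, "m1": m1, "z2": z2, "m2": m2, "z3": z3,
            "a3": a3, "keep": keep, "dropped": dropped,
        }
        return probs, logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        c = self._cache
        if c is None:
            raise RuntimeError("forward must be called before backward")
        n, k, h, w = c["a3"].shape
        dfcW = dlogits @ c["dropped"]
        dfcb = float(dlogits.sum())
        dgap = dlogits[:, None] * self.fc_W[None, :] * c["keep"]
        da3 = np.broadcast_to(dgap[:, :, None, None] / (h * w), (n, k, h, w)).copy()
        dz3 = da3 * (c["z3"] > 0)
        dp2, dc3W, dc3b = self.conv3.backward(dz3)
        da2 = _maxpool_back(dp2, c["m2"])
        dz2 = da2 * (c["z2"] > 0)
        dp1, dc2W, dc2b = self.conv2.backward(dz2)
        da1 = _maxpool_back(dp1, c["m1"])
        dz1 = da1 * (c["z1"] > 0)
        _, dc1W, dc1b = self.conv1.backward(dz1)
        return {
            "c1W": dc1W, "c1b": dc1b, "c2W": dc2W, "c2b": dc2b,
            "c3W": dc3W, "c3b": dc3b, "fcW": dfcW, "fcb": dfcb,
        }

    def feature_maps_and_gradient(
        self, image: np.ndarray, class_index: int = 1
    ) -> tuple[np.ndarray, np.ndarray]:
        """Final conv maps A (K, h, w) and dScore/dA for one image.

        The score is the pre-sigmoid logit for the melanoma class
        (class_index 1) or its negation (class_index 0).
        """
        self.forward(image, train=False)
        a3 = self._cache["a3"][0]
        k, h, w = a3.shape
        sign = 1.0 if class_index == 1 else -1.0
        # logit = fc_W . mean(A); dropout is identity at inference
        grad = sign * np.broadcast_to(
            self.fc_W[:, None, None] / (h * w), (k, h, w)
        ).copy()
        return a3, grad


class Adam:
    """Adam with L2 weight decay, matching the training configuration
    (lr 1e-4, beta1 0.9, beta2 0.999, decay 1e-5 by default)."""

    def __init__(
        self,
        model: TinyCNN,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 1e-5,
    ):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        params = model.parameters()
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.m["fcb"] = 0.0
        self.v["fcb"] = 0.0

    def step(self, grads: dict) -> None:
        self.t += 1
        params = self.model.parameters()
        params["fcb"] = self.model.fc_b
        new_fcb = None
        for k, g in grads.items():
            p = params[k]
            g = g + self.weight_decay * p
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * np.square(g)
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if k == "fcb":
                new_fcb = float(p - update)
            else:
                p -= update
        if new_fcb is not None:
            self.model.fc_b = new_fcb
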