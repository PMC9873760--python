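"""A compact convolutional rating network with inspectable ReLU layers.

The network maps an RGB canvas to a liking rating: a configurable stack of
3x3 'same' convolutions with interleaved 2x2 max-pools, two fully connected
hidden layers, and a 10-way softmax head whose probability-weighted average
of bin centres yields a scalar rating in [0, 3].  Training uses a Huber
loss and SGD with momentum 0.9, weight decay 5e-4, batch size 100, and a
step learning-rate decay (x0.1 every 30 epochs).  Inputs of arbitrary size
are scaled so the longest edge fits the canvas and zero-padded.

Implemented directly on numpy (im2col convolutions with full backprop) so
the probe analyses stay lightweight and deterministic; every post-ReLU
activation is extractable by layer index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RatingNetConfig:
    input_size: int = 32  # square canvas edge
    conv_channels: tuple[int, ...] = (4, 4, 6, 6, 8)
    pool_after: tuple[int, ...] = (1, 3, 4)  # conv indices followed by 2x2 pool
    fc_sizes: tuple[int, ...] = (32, 16)
    n_bins: int = 10
    value_range: tuple[float, float] = (0.0, 3.0)
    lr: float = 1e-4
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 100
    lr_step_epochs: int = 30
    lr_decay: float = 0.1
    huber_delta: float = 1.0

    @property
    def n_relu_layers(self) -> int:
        return len(self.conv_channels) + len(self.fc_sizes)


def preprocess_images(images, canvas: int) -> np.ndarray:
    """Scale each image's longest edge to the canvas and zero-pad.

    Accepts RasterImage objects or (H, W, 3) arrays; returns
    (N, 3, canvas, canvas) float32.
    """
    from skimage.transform import resize

    out = np.zeros((len(images), 3, canvas, canvas), dtype=np.float64)
    for i, img in enumerate(images):
        px = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
        h, w = px.shape[:2]
        scale = canvas / max(h, w)
        nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
        small = resize(px, (nh, nw, 3), order=1, anti_aliasing=True)
        out[i, :, :nh, :nw] = np.moveaxis(small, -1, 0)
    return out


# ---------------------------------------------------------------------------
# Layers (forward + backward)


class _Conv:
    """3x3 'same' convolution via im2col."""

    def __init__(self, c_in, c_out, k, rng):
        fan_in = c_in * k * k
        self.W = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def _cols(self, x):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n, c*k*k, h*w)
        return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * self.k * self.k, h * w)

    def forward(self, x):
        self.x_shape = x.shape
        self.cols = self._cols(x)
        n, _, h, w = x.shape
        out = np.einsum("of,nfp->nop", self.W, self.cols) + self.b[None, :, None]
        return out.reshape(n, -1, h, w)

    def backward(self, grad):
        n, c_out, h, w = grad.shape
        g = grad.reshape(n, c_out, h * w)
        self.gW = np.einsum("nop,nfp->of", g, self.cols) / n
        self.gb = g.sum(axis=(0, 2)) / n
        gcols = np.einsum("of,nop->nfp", self.W, g)
        # col2im
        k, p = self.k, self.k // 2
        _, c_in, H, W_ = self.x_shape
        gx = np.zeros((n, c_in, H + 2 * p, W_ + 2 * p))
        gc = gcols.reshape(n, c_in, k, k, H, W_)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + H, j : j + W_] += gc[:, :, i, j]
        return gx[:, :, p : p + H, p : p + W_]

    params = property(lambda self: [("W", self.W, "vW"), ("b", self.b, "vb")])


class _Pool:
    """2x2 max pool, stride 2."""

    def forward(self, x):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xv = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        self.x_shape = x.shape
        flat = xv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self.argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad):
        n, c, h2, w2 = grad.shape
        gx = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(gx, self.argmax[..., None], grad[..., None], axis=-1)
        gx = gx.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = gx.reshape(n, c, h2 * 2, w2 * 2)
        out = np.zeros(self.x_shape)
        out[:, :, : h2 * 2, : w2 * 2] = gx
        return out


class _ReLU:
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class _Flatten:
    def forward(self, x):
        self.x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.x_shape)


class _Linear:
    def __init__(self, d_in, d_out, rng):
        self.W = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)
        self.vW = np.zeros_like(self.W)
        self.vb = np.zeros_like(self.b)

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        n = grad.shape[0]
        self.gW = self.x.T @ grad / n
        self.gb = grad.mean(axis=0)
        return grad @ self.W.T


class RatingNet:
    """The network, with every post-ReLU activation recordable."""

    def __init__(self, config: RatingNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        layers = []
        c = 3
        size = config.input_size
        for i, c_out in enumerate(config.conv_channels):
            layers.append(_Conv(c, c_out, 3, rng))
            layers.append(_ReLU())
            c = c_out
            if i in config.pool_after:
                layers.append(_Pool())
                size //= 2
        layers.append(_Flatten())
        d = c * size * size
        for f in config.fc_sizes:
            layers.append(_Linear(d, f, rng))
            layers.append(_ReLU())
            d = f
        self.head = _Linear(d, config.n_bins, rng)
        self.layers = layers
        lo, hi = config.value_range
        self.bin_centers = np.linspace(lo, hi, config.n_bins)

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, record: bool = False):
        acts = []
        h = x
        for layer in self.layers:
            h = layer.forward(h)
            if record and isinstance(layer, _ReLU):
                acts.append(h.reshape(h.shape[0], -1).copy())
        logits = self.head.forward(h)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        self.p = e / e.sum(axis=1, keepdims=True)
        readout = self.p @ self.bin_centers
        if record:
            return readout, acts
        return readout

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    # -- training ----------------------------------------------------------

    def _backward(self, d_readout: np.ndarray):
        # d readout / d logits for the softmax-weighted average head
        r = self.p @ self.bin_centers
        dlogits = self.p * (self.bin_centers[None, :] - r[:, None])
        grad = d_readout[:, None] * dlogits
        grad = self.head.backward(grad)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _step(self, lr: float):
        cfg = self.config
        for layer in [*self.layers, self.head]:
            if not hasattr(layer, "W"):
                continue
            for name, vname, gname in (("W", "vW", "gW"), ("b", "vb", "gb")):
                p = getattr(layer, name)
                v = getattr(layer, vname)
                g = getattr(layer, gname) + cfg.weight_decay * p
                v *= cfg.momentum
                v -= lr * g
                p += v

    def train(
        self,
        images: np.ndarray,
        ratings: np.ndarray,
        epochs: int,
        seed: int = 0,
        lr: float | None = None,
        stop_correlation: float | None = None,
    ) -> list[float]:
        """SGD with momentum on the Huber loss; returns the per-epoch loss log.

        ``stop_correlation`` implements early stopping: training halts once
        the training-set Pearson correlation reaches that level (used to
        match a cross-validated benchmark before activations are extracted).
        Raises on a non-finite loss.
        """
        cfg = self.config
        y = np.asarray(ratings, dtype=float)
        rng = np.random.default_rng(seed)
        lr0 = cfg.lr if lr is None else lr
        losses = []
        n = images.shape[0]
        for epoch in range(epochs):
            cur_lr = lr0 * (cfg.lr_decay ** (epoch // cfg.lr_step_epochs))
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                pred = self.forward(images[idx])
                err = pred - y[idx]
                d = cfg.huber_delta
                small = np.abs(err) <= d
                loss = np.where(small, 0.5 * err**2, d * (np.abs(err) - 0.5 * d))
                total += float(loss.sum())
                dloss = np.clip(err, -d, d)
                self._backward(dloss)
                self._step(cur_lr)
            mean_loss = total / n
            if not np.isfinite(mean_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lower the learning rate"
                )
            losses.append(mean_loss)
            if stop_correlation is not None:
                pred = self.predict(images)
                if pred.std() > 0 and y.std() > 0:
                    r = float(np.corrcoef(pred, y)[0, 1])
                    if r >= stop_correlation:
                        break
        return losses
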