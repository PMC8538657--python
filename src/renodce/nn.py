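"""A small, deterministic CNN engine in NumPy.

Implements exactly the layers the kidney-segmentation U-Net needs —
3x3 convolution (im2col/matmul), batch normalization, dropout, 2x2 max
pooling, 2x2 transposed-convolution upsampling, skip concatenation, a
1x1 output convolution with sigmoid activation — together with explicit
backpropagation and plain SGD with momentum.  Keeping the engine in
NumPy makes training bit-reproducible for a given seed and keeps the
package free of heavyweight runtime dependencies; correctness of every
analytic gradient is verified against finite differences in the test
suite.

Tensors are float32 with layout (N, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError, StateError

__all__ = ["UNet", "SGD", "bce_loss"]

_F = np.float32


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=_F)
    dc = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + h, j : j + w] += dc[:, :, :, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2D:
    """k x k same-padded convolution, He-initialised."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)).astype(_F)
        self.b = np.zeros(cout, dtype=_F)
        self.k, self.pad = k, k // 2
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training):
        self._shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        n, _, h, w = x.shape
        out = self._cols @ self.w.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, cout, h, w = dy.shape
        dmat = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.gw += dmat.T @ self._cols
        self.gb += dmat.sum(axis=0)
        dcols = dmat @ self.w
        return _col2im(dcols, self._shape, self.k, self.pad)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class BatchNorm2D:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_F)
        self.beta = np.zeros(c, dtype=_F)
        self.running_mean = np.zeros(c, dtype=_F)
        self.running_var = np.ones(c, dtype=_F)
        self.momentum, self.eps = momentum, eps
        self.gg = np.zeros_like(self.gamma)
        self.gb = np.zeros_like(self.beta)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(_F)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * var).astype(_F)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(_F)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) * self._invstd
        self._training = training
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        self.gg += (dy * self._xhat).sum(axis=(0, 2, 3))
        self.gb += dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        if not self._training:
            return dy * g * self._invstd
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        return (self._invstd / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True)
        )

    def params(self):
        return [(self.gamma, self.gg), (self.beta, self.gb)]


class ReLU:
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)

    def params(self):
        return []


class Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ShapeError("dropout rate must lie in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(_F) / _F(1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class MaxPool2:
    def forward(self, x, training):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dy):
        n, c, h2, w2 = dy.shape
        dxr = self._mask * dy[:, :, :, None, :, None]
        return dxr.reshape(n, c, h2 * 2, w2 * 2)

    def params(self):
        return []


class ConvTranspose2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout, 2, 2)).astype(_F)
        self.b = np.zeros(cout, dtype=_F)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, training):
        self._x = x
        n, cin, h, w = x.shape
        y = np.einsum("ncij,cdab->ndiajb", x, self.w, optimize=True)
        cout = self.w.shape[1]
        return y.reshape(n, cout, 2 * h, 2 * w) + self.b[None, :, None, None]

    def backward(self, dy):
        n, cout, h2, w2 = dy.shape
        dyr = dy.reshape(n, cout, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        # dyr: (n, d, i, j, a, b)
        self.gw += np.einsum("ncij,ndijab->cdab", self._x, dyr, optimize=True)
        self.gb += dy.sum(axis=(0, 2, 3))
        return np.einsum("ndijab,cdab->ncij", dyr, self.w, optimize=True)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(y, p, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy between targets y and probabilities p."""
    y = np.asarray(y, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if y.shape != p.shape:
        raise ShapeError("targets and predictions must have the same length")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

class _Block:
    """A sequence of layers applied in order."""

    def __init__(self, layers):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


def _conv_bn_relu(cin, cout, rng, batch_norm):
    layers = [Conv2D(cin, cout, 3, rng)]
    if batch_norm:
        layers.append(BatchNorm2D(cout))
    layers.append(ReLU())
    return layers


class UNet:
    """Encoder–decoder segmentation network with skip connections.

    ``depth`` pooling levels; filter counts double from ``base_filters``
    to ``base_filters * 2**depth`` at the bottleneck and mirror back up.
    Each encoder block is conv–BN–ReLU, dropout, conv–BN–ReLU followed
    by 2x2 max pooling; decoder blocks upsample by 2x2 transposed
    convolution, concatenate the matching encoder feature map and apply
    two conv–BN–ReLU pairs (no dropout).  A 1x1 convolution with sigmoid
    yields the per-pixel kidney probability.
    """

    def __init__(
        self,
        in_channels: int = 1,
        base_filters: int = 64,
        depth: int = 4,
        dropout: float = 0.2,
        batch_norm: bool = True,
        seed: int = 0,
    ):
        self.depth = depth
        self.base_filters = base_filters
        self.dropout_rate = dropout
        self.rng = np.random.default_rng(seed)
        self.trained = False
        rng = self.rng

        self.enc_pre: list[_Block] = []   # conv-bn-relu + dropout
        self.enc_post: list[_Block] = []  # conv-bn-relu
        self.pools: list[MaxPool2] = []
        cin = in_channels
        self.encoder_filters = []
        for level in range(depth):
            cout = base_filters * 2**level
            self.encoder_filters.append(cout)
            self.enc_pre.append(_Block(_conv_bn_relu(cin, cout, rng, batch_norm) + [Dropout(dropout, rng)]))
            self.enc_post.append(_Block(_conv_bn_relu(cout, cout, rng, batch_norm)))
            self.pools.append(MaxPool2())
            cin = cout
        cbot = base_filters * 2**depth
        self.bottleneck_filters = cbot
        self.bottleneck = _Block(
            _conv_bn_relu(cin, cbot, rng, batch_norm)
            + [Dropout(dropout, rng)]
            + _conv_bn_relu(cbot, cbot, rng, batch_norm)
        )
        self.ups: list[ConvTranspose2] = []
        self.dec: list[_Block] = []
        cin = cbot
        for level in reversed(range(depth)):
            cout = base_filters * 2**level
            self.ups.append(ConvTranspose2(cin, cout, rng))
            self.dec.append(_Block(_conv_bn_relu(2 * cout, cout, rng, batch_norm)
                                   + _conv_bn_relu(cout, cout, rng, batch_norm)))
            cin = cout
        self.head = Conv2D(cin, 1, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def _check_input(self, x):
        if x.ndim != 4:
            raise ShapeError("input must be (N, C, H, W)")
        h, w = x.shape[2:]
        if h % 2**self.depth or w % 2**self.depth:
            raise ShapeError(f"input size {h}x{w} must be divisible by 2^depth = {2**self.depth}")

    def forward(self, x, training: bool = False) -> np.ndarray:
        """Per-pixel probability map in [0, 1], shape (N, 1, H, W)."""
        x = np.asarray(x, dtype=_F)
        self._check_input(x)
        skips = []
        for pre, post, pool in zip(self.enc_pre, self.enc_post, self.pools):
            x = post.forward(pre.forward(x, training), training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, training)
        self._logits = self.head.forward(x, training)
        self._probs = _sigmoid(self._logits)
        return self._probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient with respect to the output logits."""
        dy = self.head.backward(dlogits.astype(_F))
        dskips = []
        for up, dec, c_skip in zip(reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)):
            dy = dec.backward(dy)
            dskips.append(dy[:, :c_skip])
            dy = up.backward(dy[:, c_skip:])
        dy = self.bottleneck.backward(dy)
        for pre, post, pool, dskip in zip(
            reversed(self.enc_pre), reversed(self.enc_post), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy) + dskip
            dy = pre.backward(post.backward(dy))

    def train_step(self, x, y, optimizer: "SGD", eps: float = 1e-7) -> float:
        """One SGD step on a batch; returns the batch BCE loss."""
        p = self.forward(x, training=True)
        y = np.asarray(y, dtype=_F).reshape(p.shape)
        loss = bce_loss(y, p, eps)
        # d(BCE)/d(logits) for a sigmoid output: (p - y) / N
        dlogits = (p - y) / _F(p.size)
        self.backward(dlogits)
        optimizer.step()
        return loss

    def modules(self):
        mods = self.enc_pre + self.enc_post + self.pools + [self.bottleneck]
        mods += self.ups + self.dec + [self.head]
        return mods

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def get_weights(self):
        state = [w.copy() for w, _ in self.params()]
        bn_state = []
        for m in self.modules():
            layers = m.layers if isinstance(m, _Block) else [m]
            for layer in layers:
                if isinstance(layer, BatchNorm2D):
                    bn_state.append((layer.running_mean.copy(), layer.running_var.copy()))
        return state, bn_state

    def set_weights(self, state) -> None:
        weights, bn_state = state
        for (w, _), saved in zip(self.params(), weights):
            w[...] = saved
        i = 0
        for m in self.modules():
            layers = m.layers if isinstance(m, _Block) else [m]
            for layer in layers:
                if isinstance(layer, BatchNorm2D):
                    layer.running_mean[...] = bn_state[i][0]
                    layer.running_var[...] = bn_state[i][1]
                    i += 1

    def require_trained(self) -> None:
        if not self.trained:
            raise StateError("network has not been trained")


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.99):
        if lr <= 0:
            raise ShapeError("learning rate must be positive")
        self.params = params
        self.lr, self.momentum = lr, momentum
        self.velocity = [np.zeros_like(w) for w, _ in params]

    def step(self) -> None:
        for (w, g), v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            w += v
            g[...] = 0.0
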