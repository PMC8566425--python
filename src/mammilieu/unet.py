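"""A small encoder-decoder convolutional network in pure numpy.

Architecture family: U-shaped encoder-decoder with skip connections,
3x3 convolutions, ReLU activations (f(x) = max(0, x)), 2x2 average-pool
downsampling and nearest-neighbour upsampling, closed by a 1x1 convolution
to per-pixel class logits.  Width and depth are configurable; the defaults
are deliberately narrow so that training on synthetic tiles runs in
seconds to minutes on one CPU.

Gradients are computed by hand (im2col convolutions) and parameters are
updated with Adam.  All randomness flows through a seeded Generator, so
training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TinyUNet", "softmax_cross_entropy"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, H, W) -> (H*W, C*9) patch matrix for a 3x3 same convolution."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    cols = np.empty((c, 9, h, w), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, k] = xp[:, dy : dy + h, dx : dx + w]
            k += 1
    return cols.reshape(c * 9, h * w).T


def _col2im(gcols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    g = gcols.T.reshape(c, 9, h, w)
    gxp = np.zeros((c, h + 2, w + 2), dtype=gcols.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            gxp[:, dy : dy + h, dx : dx + w] += g[:, k]
            k += 1
    return gxp[:, 1 : h + 1, 1 : w + 1]


class _Adam:
    def __init__(self, shape, lr=1e-3):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0
        self.lr = lr

    def step(self, p, g):
        self.t += 1
        self.m = 0.9 * self.m + 0.1 * g
        self.v = 0.999 * self.v + 0.001 * g * g
        mh = self.m / (1 - 0.9**self.t)
        vh = self.v / (1 - 0.999**self.t)
        p -= self.lr * mh / (np.sqrt(vh) + 1e-8)


class _Conv:
    """kxk same convolution (+ optional ReLU); k in {1, 3}."""

    def __init__(self, cin, cout, rng, k=3, relu=True, lr=1e-3):
        self.cin, self.cout, self.k, self.relu = cin, cout, k, relu
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in))
        self.b = np.zeros(cout)
        self.optW, self.optb = _Adam(self.W.shape, lr), _Adam(self.b.shape, lr)

    def forward(self, x):
        c, h, w = x.shape
        cols = _im2col(x) if self.k == 3 else x.reshape(c, -1).T
        out = cols @ self.W.T + self.b
        y = out.T.reshape(self.cout, h, w)
        mask = None
        if self.relu:
            mask = y > 0
            y = np.where(mask, y, 0.0)
        self._cache = (cols, mask, (c, h, w))
        return y

    def backward(self, gy):
        cols, mask, (c, h, w) = self._cache
        if self.relu:
            gy = np.where(mask, gy, 0.0)
        g = gy.reshape(self.cout, -1)
        gW = g @ cols
        gb = g.sum(axis=1)
        gcols = g.T @ self.W
        gx = _col2im(gcols, c, h, w) if self.k == 3 else gcols.T.reshape(c, h, w)
        self.optW.step(self.W, gW)
        self.optb.step(self.b, gb)
        return gx


def _pool2(x):
    c, h, w = x.shape
    return x.reshape(c, h // 2, 2, w // 2, 2).mean(axis=(2, 4))


def _pool2_back(g):
    return np.repeat(np.repeat(g, 2, axis=1), 2, axis=2) / 4.0


def _up2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _up2_back(g):
    c, h, w = g.shape
    return g.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


def softmax_cross_entropy(logits, target, weight):
    """Per-pixel softmax CE.  logits (K,H,W); target (H,W) int;
    weight (H,W) float (0 excludes a pixel).  Returns (loss, grad)."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=0, keepdims=True)
    h, w = target.shape
    idx = (target.ravel(), np.arange(h * w))
    logp = np.log(p.reshape(p.shape[0], -1)[idx] + 1e-12).reshape(h, w)
    wsum = weight.sum()
    if wsum <= 0:
        return 0.0, np.zeros_like(logits)
    loss = -(weight * logp).sum() / wsum
    grad = p.copy().reshape(p.shape[0], -1)
    grad[idx] -= 1.0
    grad = grad.reshape(logits.shape) * (weight / wsum)[None]
    return float(loss), grad


class TinyUNet:
    """Encoder-decoder with skip connections; depth = number of poolings.

    Input tile sides must be divisible by 2**depth.
    """

    def __init__(self, in_ch=3, n_classes=2, base=8, depth=2, lr=1e-3, seed=0):
        rng = np.random.default_rng(seed)
        self.in_ch, self.n_classes, self.base, self.depth = in_ch, n_classes, base, depth
        ch = [base * 2**d for d in range(depth + 1)]
        self.enc = []
        cin = in_ch
        for d in range(depth):
            self.enc.append(
                [_Conv(cin, ch[d], rng, lr=lr), _Conv(ch[d], ch[d], rng, lr=lr)]
            )
            cin = ch[d]
        self.bott = _Conv(cin, ch[depth], rng, lr=lr)
        self.dec = []
        cin = ch[depth]
        for d in reversed(range(depth)):
            self.dec.append(_Conv(cin + ch[d], ch[d], rng, lr=lr))
            cin = ch[d]
        self.head = _Conv(cin, n_classes, rng, k=1, relu=False, lr=lr)

    def forward(self, x):
        """x: (in_ch, H, W) -> logits (n_classes, H, W)."""
        skips = []
        for convs in self.enc:
            for cv in convs:
                x = cv.forward(x)
            skips.append(x)
            x = _pool2(x)
        x = self.bott.forward(x)
        self._skip_ch = []
        for cv, skip in zip(self.dec, reversed(skips)):
            x = _up2(x)
            self._skip_ch.append((x.shape[0], skip.shape[0]))
            x = cv.forward(np.concatenate([x, skip], axis=0))
        return self.head.forward(x)

    def backward(self, grad):
        grad = self.head.backward(grad)
        skip_grads = []
        for cv, (c_up, c_skip) in zip(reversed(self.dec), reversed(self._skip_ch)):
            g = cv.backward(grad)
            skip_grads.append(g[c_up:])
            grad = _up2_back(g[:c_up])
        grad = self.bott.backward(grad)
        for convs, gskip in zip(reversed(self.enc), reversed(skip_grads)):
            grad = _pool2_back(grad) + gskip
            for cv in reversed(convs):
                grad = cv.backward(grad)
        return grad

    def predict_proba(self, x):
        logits = self.forward(x)
        z = logits - logits.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    # -- checkpointing ------------------------------------------------
    def _layers(self):
        out = [cv for convs in self.enc for cv in convs]
        out.append(self.bott)
        out.extend(self.dec)
        out.append(self.head)
        return out

    def state_dict(self):
        state = {"meta": np.array([self.in_ch, self.n_classes, self.base, self.depth])}
        for i, cv in enumerate(self._layers()):
            state[f"W{i}"] = cv.W
            state[f"b{i}"] = cv.b
        return state

    @classmethod
    def from_state(cls, state):
        in_ch, n_classes, base, depth = (int(v) for v in state["meta"])
        net = cls(in_ch=in_ch, n_classes=n_classes, base=base, depth=depth)
        for i, cv in enumerate(net._layers()):
            cv.W = np.asarray(state[f"W{i}"])
            cv.b = np.asarray(state[f"b{i}"])
        return net
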