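"""Minimal convolutional network framework (numpy, single sample, batch = 1).

The image translator trains with batch size 1, so every tensor here is
``(C, H, W)``.  Layers are functional: ``forward`` returns ``(output, cache)``
and ``backward(grad, cache)`` accumulates parameter gradients and returns the
input gradient, which allows several live forward passes through the same
module (the discriminator is evaluated on real and fake inputs per step).

Convolutions use 4x4 kernels with stride 2 (down) or transposed stride 2 (up),
the Pix2Pix convention.  Batch normalization with batch 1 reduces to instance
normalization: statistics are always the current sample's, in training and
inference alike.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------

def _out_size(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def _im2col(xpad: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    c = xpad.shape[0]
    col = np.empty((c, k, k, ho, wo), dtype=DTYPE)
    for u in range(k):
        for v in range(k):
            col[:, u, v] = xpad[:, u : u + s * ho : s, v : v + s * wo : s]
    return col.reshape(c * k * k, ho * wo)


def _col2im(gcol: np.ndarray, c: int, hpad: int, wpad: int, k: int, s: int,
            ho: int, wo: int) -> np.ndarray:
    g = np.zeros((c, hpad, wpad), dtype=DTYPE)
    gcol = gcol.reshape(c, k, k, ho, wo)
    for u in range(k):
        for v in range(k):
            g[:, u : u + s * ho : s, v : v + s * wo : s] += gcol[:, u, v]
    return g


def conv2d_forward(x, w, b, s, p):
    """x: (C,H,W); w: (F, C, k, k) -> (F, Ho, Wo) plus the im2col cache."""
    f, c, k, _ = w.shape
    h, wd = x.shape[1:]
    ho, wo = _out_size(h, k, s, p), _out_size(wd, k, s, p)
    xpad = np.pad(x, ((0, 0), (p, p), (p, p)))
    col = _im2col(xpad, k, s, ho, wo)
    y = w.reshape(f, -1) @ col
    if b is not None:
        y += b[:, None]
    return y.reshape(f, ho, wo), (col, x.shape, xpad.shape)


def conv2d_backward(gy, w, cache, s, p):
    col, xshape, padshape = cache
    f, c, k, _ = w.shape
    ho, wo = gy.shape[1:]
    gmat = gy.reshape(f, -1)
    gw = (gmat @ col.T).reshape(w.shape)
    gb = gmat.sum(axis=1)
    gcol = w.reshape(f, -1).T @ gmat
    gx = _col2im(gcol, c, padshape[1], padshape[2], k, s, ho, wo)
    if p:
        gx = gx[:, p:-p, p:-p]
    return gx, gw, gb


def convT2d_forward(x, w, b, s, p):
    """Transposed conv; x: (Cin,H,W); w: (Cin, Cout, k, k) -> (Cout, s*H, s*W)."""
    cin, cout, k, _ = w.shape
    h, wd = x.shape[1:]
    ho, wo = s * (h - 1) + k - 2 * p, s * (wd - 1) + k - 2 * p
    xmat = x.reshape(cin, -1)
    gcol = w.reshape(cin, -1).T @ xmat
    y = _col2im(gcol, cout, ho + 2 * p, wo + 2 * p, k, s, h, wd)
    if p:
        y = y[:, p:-p, p:-p]
    if b is not None:
        y = y + b[:, None, None]
    return y, (x, (ho, wo))


def convT2d_backward(gy, w, cache, s, p):
    x, _ = cache
    cin, cout, k, _ = w.shape
    h, wd = x.shape[1:]
    gypad = np.pad(gy, ((0, 0), (p, p), (p, p)))
    col = _im2col(gypad, k, s, h, wd)
    gx = (w.reshape(cin, -1) @ col).reshape(x.shape)
    gw = (x.reshape(cin, -1) @ col.T).reshape(w.shape)
    gb = gy.sum(axis=(1, 2))
    return gx, gw, gb


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, *, train: bool, rng: np.random.Generator):
        raise NotImplementedError

    def backward(self, gy, cache):
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, cin, cout, rng, k=4, s=2, p=1, init_sd=0.02):
        self.k, self.s, self.p = k, s, p
        self.w = Param(rng.normal(0.0, init_sd, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, *, train, rng):
        return conv2d_forward(x, self.w.value, self.b.value, self.s, self.p)

    def backward(self, gy, cache):
        gx, gw, gb = conv2d_backward(gy, self.w.value, cache, self.s, self.p)
        self.w.grad += gw
        self.b.grad += gb
        return gx


class ConvTranspose2d(Layer):
    def __init__(self, cin, cout, rng, k=4, s=2, p=1, init_sd=0.02):
        self.k, self.s, self.p = k, s, p
        self.w = Param(rng.normal(0.0, init_sd, size=(cin, cout, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, *, train, rng):
        return convT2d_forward(x, self.w.value, self.b.value, self.s, self.p)

    def backward(self, gy, cache):
        gx, gw, gb = convT2d_backward(gy, self.w.value, cache, self.s, self.p)
        self.w.grad += gw
        self.b.grad += gb
        return gx


class InstanceBN(Layer):
    """Batch normalization at batch size 1 (per-channel spatial statistics)."""

    def __init__(self, c, rng, eps=1e-5):
        self.eps = eps
        self.gamma = Param(rng.normal(1.0, 0.02, size=c))
        self.beta = Param(np.zeros(c))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, *, train, rng):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        y = self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]
        return y.astype(DTYPE), (xhat, inv)

    def backward(self, gy, cache):
        xhat, inv = cache
        self.gamma.grad += (gy * xhat).sum(axis=(1, 2))
        self.beta.grad += gy.sum(axis=(1, 2))
        g = gy * self.gamma.value[:, None, None]
        m1 = g.mean(axis=(1, 2), keepdims=True)
        m2 = (g * xhat).mean(axis=(1, 2), keepdims=True)
        return (inv * (g - m1 - xhat * m2)).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.2):
        self.alpha = alpha

    def forward(self, x, *, train, rng):
        y = np.where(x >= 0, x, self.alpha * x).astype(DTYPE)
        return y, x >= 0

    def backward(self, gy, cache):
        return np.where(cache, gy, self.alpha * gy).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, *, train, rng):
        return np.maximum(x, 0.0).astype(DTYPE), x > 0

    def backward(self, gy, cache):
        return (gy * cache).astype(DTYPE)


class Tanh(Layer):
    def forward(self, x, *, train, rng):
        y = np.tanh(x).astype(DTYPE)
        return y, y

    def backward(self, gy, cache):
        return (gy * (1.0 - cache * cache)).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; the GAN keeps it active at inference as its noise z."""

    def __init__(self, rate=0.5):
        self.rate = rate

    def forward(self, x, *, train, rng):
        if not train or self.rate <= 0.0:
            return x, None
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        mask = mask.astype(DTYPE)
        return x * mask, mask

    def backward(self, gy, cache):
        if cache is None:
            return gy
        return gy * cache


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, *, train, rng):
        caches = []
        for l in self.layers:
            x, c = l.forward(x, train=train, rng=rng)
            caches.append(c)
        return x, caches

    def backward(self, gy, caches):
        for l, c in zip(reversed(self.layers), reversed(caches)):
            gy = l.backward(gy, c)
        return gy


# ---------------------------------------------------------------------------
# U-net generator
# ---------------------------------------------------------------------------

class UNet:
    """Encoder-decoder with skip connections and tanh output.

    For an input of side ``2^d`` there are ``d`` encoder blocks (conv + BN +
    leaky ReLU; no BN on the first block nor on the 1x1 bottleneck, where
    per-sample normalization is degenerate), ``d - 1`` decoder blocks
    (transposed conv + BN + dropout on the first ``n_dropout`` + ReLU) and a
    final transposed conv + tanh.  Filter counts double per level, capped at
    ``8 * base``.
    """

    def __init__(self, in_ch=3, out_ch=3, size=256, base=64,
                 dropout_rate=0.5, n_dropout=3, rng=None):
        rng = rng or np.random.default_rng(0)
        d = int(round(np.log2(size)))
        if 2**d != size or d < 2:
            raise ValueError("input size must be a power of two >= 4")
        self.size, self.depth, self.out_ch = size, d, out_ch
        ec = [base * min(2**i, 8) for i in range(d)]
        self.enc = []
        prev = in_ch
        for i in range(d):
            layers = [Conv2d(prev, ec[i], rng)]
            if 0 < i < d - 1:
                layers.append(InstanceBN(ec[i], rng))
            layers.append(LeakyReLU(0.2))
            self.enc.append(Sequential(layers))
            prev = ec[i]
        self.dec = []
        dc = [ec[d - 2 - j] for j in range(d - 1)]
        for j in range(d - 1):
            cin = ec[d - 1] if j == 0 else dc[j - 1] + ec[d - 1 - j]
            layers = [ConvTranspose2d(cin, dc[j], rng), InstanceBN(dc[j], rng)]
            if j < n_dropout:
                layers.append(Dropout(dropout_rate))
            layers.append(ReLU())
            self.dec.append(Sequential(layers))
        self.final = Sequential(
            [ConvTranspose2d(dc[-1] + ec[0], out_ch, rng), Tanh()]
        )

    def params(self) -> list[Param]:
        out = []
        for m in self.enc + self.dec + [self.final]:
            out.extend(m.params())
        return out

    def forward(self, x, *, train: bool, rng: np.random.Generator):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.shape[1] != self.size or x.shape[2] != self.size:
            raise ValueError(f"expected {self.size}x{self.size} input, got {x.shape}")
        skips, ecaches = [], []
        h = x
        for m in self.enc:
            h, c = m.forward(h, train=train, rng=rng)
            skips.append(h)
            ecaches.append(c)
        dcaches, dins = [], []
        for j, m in enumerate(self.dec):
            hin = h if j == 0 else np.concatenate([h, skips[self.depth - 1 - j]])
            dins.append(hin.shape[0] - (0 if j == 0 else skips[self.depth - 1 - j].shape[0]))
            h, c = m.forward(hin, train=train, rng=rng)
            dcaches.append(c)
        fin = np.concatenate([h, skips[0]])
        y, fcache = self.final.forward(fin, train=train, rng=rng)
        return y, (ecaches, dcaches, fcache, dins, [s.shape[0] for s in skips])

    def backward(self, gy, cache):
        ecaches, dcaches, fcache, dins, skip_ch = cache
        d = self.depth
        g = self.final.backward(gy, fcache)
        gh, gskip0 = g[: -skip_ch[0]], g[-skip_ch[0] :]
        skip_grads: list[np.ndarray | None] = [None] * d
        skip_grads[0] = gskip0
        for j in reversed(range(len(self.dec))):
            g = self.dec[j].backward(gh, dcaches[j])
            if j == 0:
                gh = g  # gradient w.r.t. the bottleneck output e_{d-1}
            else:
                gh, gs = g[: dins[j]], g[dins[j] :]
                skip_grads[d - 1 - j] = gs
        g = gh
        for i in reversed(range(d)):
            if i < d - 1 and skip_grads[i] is not None:
                g = g + skip_grads[i]
            g = self.enc[i].backward(g, ecaches[i])
        return g


# ---------------------------------------------------------------------------
# PatchGAN discriminator
# ---------------------------------------------------------------------------

class PatchGAN:
    """Patch classifier: stride-2 conv blocks, one stride-1 block, 1-channel logits.

    With the default three stride-2 blocks each output logit has a 70x70
    receptive field; a 256x256 input yields a 30x30 patch score map.
    """

    def __init__(self, in_ch=6, base=64, n_strided=3, rng=None):
        rng = rng or np.random.default_rng(0)
        layers: list[Layer] = []
        prev = in_ch
        for i in range(n_strided):
            c = base * min(2**i, 8)
            layers.append(Conv2d(prev, c, rng, s=2))
            if i > 0:
                layers.append(InstanceBN(c, rng))
            layers.append(LeakyReLU(0.2))
            prev = c
        c = base * min(2**n_strided, 8)
        layers += [Conv2d(prev, c, rng, s=1), InstanceBN(c, rng), LeakyReLU(0.2)]
        layers.append(Conv2d(c, 1, rng, s=1))
        self.net = Sequential(layers)
        self.n_strided = n_strided

    @property
    def receptive_field(self) -> int:
        rf = 1
        for s in [1, 1] + [2] * self.n_strided:
            rf = rf * s + (4 - s)
        return rf

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x, *, train: bool, rng: np.random.Generator):
        y, c = self.net.forward(np.ascontiguousarray(x, dtype=DTYPE), train=train, rng=rng)
        return y[0], c  # drop the singleton channel axis -> (Ho, Wo)

    def backward(self, gy, cache):
        return self.net.backward(gy[None], cache)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Param], lr: float, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * (p.grad * p.grad)
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
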