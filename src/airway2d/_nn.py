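"""Minimal CPU neural-network engine for the U-Net segmenter.

Implements exactly the layers the encoder-decoder needs — 3x3 convolution
(im2col), batch normalisation, ReLU, 2x2 max-pooling, x2 bilinear
upsampling, channel concatenation, a 1x1 output convolution and a softmax
cross-entropy loss — each with an explicit backward pass, plus an Adam
optimiser.  Everything is plain numpy in float32; determinism follows from
seeding a single ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*9) patches for a 3x3, pad-1 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * 9)


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "conv"):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = Param(
            (rng.normal(0, scale, (c_out, c_in * 9))).astype(DTYPE),
            f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=DTYPE), f"{name}.b")
        self.c_in, self.c_out = c_in, c_out
        self._cols = None
        self._shape = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        out = cols @ self.W.value.T + self.b.value
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            n * h * w, self.c_out)
        self.W.grad += g2.T @ self._cols
        self.b.grad += g2.sum(axis=0)
        # grad wrt input: correlate g with the spatially flipped kernel,
        # swapping in/out channels
        Wk = self.W.value.reshape(self.c_out, self.c_in, 3, 3)
        Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.c_in, self.c_out * 9)
        gcols = _im2col(g)
        dx = gcols @ Wflip.T
        self._cols = None
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "head"):
        scale = np.sqrt(2.0 / c_in)
        self.W = Param(rng.normal(0, scale, (c_out, c_in)).astype(DTYPE),
                       f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=DTYPE), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return np.einsum("oc,nchw->nohw", self.W.value, x,
                         optimize=True) + self.b.value[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += np.einsum("nohw,nchw->oc", g, self._x, optimize=True)
        self.b.grad += g.sum(axis=(0, 2, 3))
        dx = np.einsum("oc,nohw->nchw", self.W.value, g, optimize=True)
        self._x = None
        return dx


class BatchNorm:
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, c: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=DTYPE), f"{name}.gamma")
        self.beta = Param(np.zeros(c, dtype=DTYPE), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * ivar[None, :, None, None]
        if train:
            self._cache = (xhat, ivar.astype(x.dtype))
        return (self.gamma.value[None, :, None, None] * xhat
                + self.beta.value[None, :, None, None])

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        n, c, h, w = g.shape
        m = n * h * w
        sg = g.sum(axis=(0, 2, 3))
        sgx = (g * xhat).sum(axis=(0, 2, 3))
        self.gamma.grad += sgx
        self.beta.grad += sg
        coef = (self.gamma.value * ivar / m)[None, :, None, None]
        dx = coef * (m * g - sg[None, :, None, None]
                     - xhat * sgx[None, :, None, None])
        self._cache = None
        return dx.astype(g.dtype)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        dx = g * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2.  Ties share the gradient equally."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            counts = mask.sum(axis=(3, 5), keepdims=True)
            self._cache = (mask / counts, (n, c, h, w))
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        mask, (n, c, h, w) = self._cache
        dx = (mask * g[:, :, :, None, :, None]).reshape(n, c, h, w)
        self._cache = None
        return dx.astype(g.dtype)


def _smooth_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """[1,2,1]/4 smoothing along one axis, zero boundary (self-adjoint)."""
    pad = [(0, 0)] * x.ndim
    pad[axis] = (1, 1)
    xp = np.pad(x, pad)
    sl = [slice(None)] * x.ndim
    lo, mid, hi = list(sl), list(sl), list(sl)
    n = x.shape[axis]
    lo[axis] = slice(0, n)
    mid[axis] = slice(1, n + 1)
    hi[axis] = slice(2, n + 2)
    return (0.25 * xp[tuple(lo)] + 0.5 * xp[tuple(mid)]
            + 0.25 * xp[tuple(hi)])


class UpBilinear2:
    """x2 upsampling: nearest repeat followed by [1,2,1]/4 smoothing in each
    axis, which realises half-pixel bilinear interpolation."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        r = x.repeat(2, axis=2).repeat(2, axis=3)
        return _smooth_axis(_smooth_axis(r, 2), 3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gs = _smooth_axis(_smooth_axis(g, 2), 3)
        n, c, h2, w2 = gs.shape
        return gs.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """``n_convs`` x (Conv3x3 -> BatchNorm -> ReLU)."""

    def __init__(self, c_in: int, c_out: int, n_convs: int,
                 rng: np.random.Generator, name: str):
        self.layers = []
        c = c_in
        for i in range(n_convs):
            self.layers += [
                Conv3x3(c, c_out, rng, f"{name}.conv{i}"),
                BatchNorm(c_out, f"{name}.bn{i}"),
                ReLU(),
            ]
            c = c_out

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class UNet:
    """Encoder-decoder with skip connections.

    ``depth_levels`` encoder levels (channels doubling from
    ``base_channels``), a bottleneck, and a mirrored decoder whose blocks
    consume the upsampled features concatenated with the skip at that
    level.  ``convs_per_block`` is 2 for the shallow variant and 4 for the
    deep one.  The head is a 1x1 convolution to ``num_classes`` scores.
    """

    def __init__(self, in_channels: int = 1, num_classes: int = 4,
                 base_channels: int = 32, depth_levels: int = 4,
                 convs_per_block: int = 2, seed: int = 0):
        if convs_per_block not in (2, 4):
            raise ValueError("convs_per_block must be 2 or 4")
        if depth_levels < 1:
            raise ValueError("depth_levels must be >= 1")
        rng = np.random.default_rng(seed)
        self.config = dict(in_channels=in_channels, num_classes=num_classes,
                           base_channels=base_channels,
                           depth_levels=depth_levels,
                           convs_per_block=convs_per_block, seed=seed)
        L, b = depth_levels, base_channels
        self.enc = []
        c = in_channels
        for i in range(L):
            self.enc.append(ConvBlock(c, b * 2**i, convs_per_block, rng,
                                      f"enc{i}"))
            c = b * 2**i
        self.bottleneck = ConvBlock(c, b * 2**L, convs_per_block, rng, "bott")
        self.pools = [MaxPool2() for _ in range(L)]
        self.ups = [UpBilinear2() for _ in range(L)]
        self.dec = []
        for i in reversed(range(L)):
            c_in = b * 2**(i + 1) + b * 2**i
            self.dec.append(ConvBlock(c_in, b * 2**i, convs_per_block, rng,
                                      f"dec{i}"))
        self.head = Conv1x1(b, num_classes, rng)
        self._split = None

    def params(self):
        ps = []
        for blk in self.enc + [self.bottleneck] + self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, C, H, W) image batch -> (N, num_classes, H, W) scores.
        H and W must be divisible by 2**depth_levels."""
        L = len(self.enc)
        if x.shape[2] % 2**L or x.shape[3] % 2**L:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by {2**L}")
        skips = []
        h = x.astype(DTYPE)
        for i, blk in enumerate(self.enc):
            h = blk.forward(h, train)
            skips.append(h)
            h = self.pools[i].forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._split = []
        for j, blk in enumerate(self.dec):
            skip = skips[L - 1 - j]
            h = self.ups[j].forward(h, train)
            self._split.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = blk.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, g: np.ndarray) -> None:
        L = len(self.enc)
        g = self.head.backward(g)
        skip_grads = [None] * L
        for j in reversed(range(L)):
            g = self.dec[j].backward(g)
            cs = self._split[j]
            skip_grads[L - 1 - j] = g[:, :cs]
            g = self.ups[j].backward(g[:, cs:])
        g = self.bottleneck.backward(g)
        for i in reversed(range(L)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    # -- persistence ---------------------------------------------------

    def state_dict(self) -> dict:
        state = {p.name: p.value for p in self.params()}
        bns = [l for blk in self.enc + [self.bottleneck] + self.dec
               for l in blk.layers if isinstance(l, BatchNorm)]
        for bn in bns:
            state[bn.gamma.name.replace(".gamma", ".running_mean")] = \
                bn.running_mean
            state[bn.gamma.name.replace(".gamma", ".running_var")] = \
                bn.running_var
        return state

    def load_state_dict(self, state: dict) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        bns = [l for blk in self.enc + [self.bottleneck] + self.dec
               for l in blk.layers if isinstance(l, BatchNorm)]
        for bn in bns:
            bn.running_mean[...] = state[
                bn.gamma.name.replace(".gamma", ".running_mean")]
            bn.running_var[...] = state[
                bn.gamma.name.replace(".gamma", ".running_var")]


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          class_weights: np.ndarray | None = None
                          ) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross entropy and its gradient wrt the logits.

    ``targets`` holds integer class ids, shape (N, H, W).  Optional
    ``class_weights`` rescale each pixel's contribution by its true class.
    """
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    idx = (np.arange(n)[:, None, None], targets,
           np.arange(h)[None, :, None], np.arange(w)[None, None, :])
    pt = p[idx[0], targets, idx[2], idx[3]]
    logpt = np.log(np.maximum(pt, 1e-12))
    if class_weights is None:
        wpix = np.ones_like(logpt)
    else:
        wpix = np.asarray(class_weights, dtype=logits.dtype)[targets]
    wsum = wpix.sum()
    loss = float(-(wpix * logpt).sum() / wsum)
    onehot = np.zeros_like(p)
    onehot[idx[0], targets, idx[2], idx[3]] = 1.0
    grad = (p - onehot) * wpix[:, None] / wsum
    return loss, grad.astype(logits.dtype)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr < 0:
            raise ValueError("lr must be >= 0")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= (self.lr * (m / b1t)
                        / (np.sqrt(v / b2t) + self.eps)).astype(p.value.dtype)
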