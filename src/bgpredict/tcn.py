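"""Temporal convolutional network building blocks in plain numpy.

Implements causal dilated 1-D convolution, the two-conv residual block, and
encoder/decoder stacks, each with a hand-written backward pass so the model
can be trained without a deep-learning framework.  Sequences are arrays of
shape ``(batch, time, channels)`` in float32.

The dilated causal convolution computes, per output channel,

    F(s) = sum_{i=0}^{k-1} f(i) . x_{s - d i}

with the input left-padded by ``(k-1) d`` zeros so output length equals
input length and no output depends on future inputs.  One stack of residual
blocks with dilations ``(1, 2, 4)`` and kernel 2 (two convolutions per
block) has receptive field ``1 + 2 (k-1) (1+2+4) = 15`` samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32


@dataclass(frozen=True)
class TCNConfig:
    """Hyper-parameters of one TCN stack."""

    kernel_size: int = 2
    n_filters: int = 64
    dilations: tuple = (1, 2, 4)
    spatial_dropout_rate: float = 0.2
    use_normalization: bool = False
    n_stacks: int = 1

    def __post_init__(self):
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be strictly positive")
        if not (0.0 <= self.spatial_dropout_rate < 1.0):
            raise ValueError("spatial_dropout_rate must lie in [0, 1)")

    @property
    def receptive_field(self) -> int:
        """Number of input samples one output sample can depend on."""
        per_stack = 2 * (self.kernel_size - 1) * sum(self.dilations)
        return 1 + self.n_stacks * per_stack


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


def causal_dilated_conv(x, weights, dilation: int):
    """Reference dilated causal convolution for a single-channel sequence.

    ``x`` is a 1-D sequence, ``weights`` the filter taps ``f(0) ... f(k-1)``
    where tap ``i`` multiplies the input ``d*i`` steps in the past; the input
    is zero-padded on the left so the output has the same length.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    if weights.ndim != 1 or len(weights) < 1:
        raise ValueError("filter must be a non-empty 1-D tap vector")
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("input sequence must be non-empty and 1-D")
    k = len(weights)
    pad = (k - 1) * dilation
    xp = np.concatenate([np.zeros(pad), x])
    out = np.zeros_like(x)
    for i in range(k):
        out += weights[i] * xp[pad - dilation * i: pad - dilation * i + len(x)]
    return out


class CausalConv1D:
    """Causal dilated convolution over (batch, time, channels) tensors.

    The k taps are gathered into a single ``(time, k*in_ch)`` design so the
    whole layer is one GEMM per direction.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator, name: str = "conv"):
        if kernel_size < 1 or dilation < 1:
            raise ValueError("kernel_size and dilation must be >= 1")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.d = kernel_size, dilation
        fan_in = kernel_size * in_ch
        scale = np.sqrt(2.0 / fan_in)  # He init: ReLU stacks downstream
        self.W = Param(rng.normal(0.0, scale, (fan_in, out_ch)), f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self._cols = None

    def params(self):
        return [self.W, self.b]

    def _gather(self, x):
        """(B, T, k*C) design: column block i holds x shifted d*i into the past."""
        B, T, C = x.shape
        cols = np.empty((B, T, self.k * C), dtype=DTYPE)
        for i in range(self.k):
            shift = self.d * i
            block = cols[:, :, i * C:(i + 1) * C]
            if shift >= T:
                block[...] = 0.0
            else:
                block[:, :shift, :] = 0.0
                block[:, shift:, :] = x[:, :T - shift, :]
        return cols

    def forward(self, x, training: bool = False):
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        cols = self._gather(np.ascontiguousarray(x, dtype=DTYPE))
        self._cols = cols
        B, T, _ = cols.shape
        out = cols.reshape(B * T, -1) @ self.W.value + self.b.value
        return out.reshape(B, T, self.out_ch)

    def backward(self, gy):
        cols = self._cols
        B, T, _ = gy.shape
        g2 = np.ascontiguousarray(gy, dtype=DTYPE).reshape(B * T, self.out_ch)
        self.W.grad += cols.reshape(B * T, -1).T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = (g2 @ self.W.value.T).reshape(B, T, self.k * self.in_ch)
        pad = (self.k - 1) * self.d
        gxp = np.zeros((B, T + pad, self.in_ch), dtype=DTYPE)
        C = self.in_ch
        for i in range(self.k):
            start = pad - self.d * i
            gxp[:, start:start + T, :] += gcols[:, :, i * C:(i + 1) * C]
        return gxp[:, pad:, :]


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class SpatialDropout1D:
    """Drops whole feature maps (channels) with probability p during training.

    Kept activations are rescaled by 1/(1-p) (inverted dropout), so inference
    needs no scaling and expectation over training passes matches the
    inference output.
    """

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def params(self):
        return []

    def forward(self, x, training: bool = False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        B, _, C = x.shape
        keep = (self.rng.random((B, 1, C)) >= self.rate).astype(DTYPE)
        self._mask = keep / (1.0 - self.rate)
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class LayerNorm:
    """Per-timestep layer normalization over channels (optional, off by default)."""

    def __init__(self, n_ch: int, name: str = "ln"):
        self.gamma = Param(np.ones(n_ch), f"{name}.gamma")
        self.beta = Param(np.zeros(n_ch), f"{name}.beta")
        self.eps = 1e-5
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training: bool = False):
        mu = x.mean(axis=2, keepdims=True)
        var = x.var(axis=2, keepdims=True)
        xhat = (x - mu) / np.sqrt(var + self.eps)
        self._cache = (xhat, var)
        return (self.gamma.value * xhat + self.beta.value).astype(DTYPE)

    def backward(self, gy):
        xhat, var = self._cache
        C = gy.shape[2]
        self.gamma.grad += (gy * xhat).sum(axis=(0, 1))
        self.beta.grad += gy.sum(axis=(0, 1))
        gxhat = gy * self.gamma.value
        inv = 1.0 / np.sqrt(var + self.eps)
        gx = (gxhat - gxhat.mean(axis=2, keepdims=True)
              - xhat * (gxhat * xhat).mean(axis=2, keepdims=True)) * inv
        return gx.astype(DTYPE)


class ResidualBlock:
    """Two causal convolutions (same dilation and kernel) with a skip path.

    Each convolution is followed by optional layer normalization, ReLU and
    1-D spatial dropout; a 1x1 convolution on the skip path matches widths
    when input and output channel counts differ.  Output = branch + skip,
    realizing H(x) = F(x) + x.
    """

    def __init__(self, in_ch: int, config: TCNConfig, dilation: int,
                 rng: np.random.Generator, name: str = "block"):
        n = config.n_filters
        self.layers = []
        ch = in_ch
        for j in (1, 2):
            self.layers.append(CausalConv1D(ch, n, config.kernel_size,
                                            dilation, rng, f"{name}.conv{j}"))
            if config.use_normalization:
                self.layers.append(LayerNorm(n, f"{name}.ln{j}"))
            self.layers.append(ReLU())
            self.layers.append(SpatialDropout1D(config.spatial_dropout_rate, rng))
            ch = n
        self.skip = None
        if in_ch != n:
            self.skip = CausalConv1D(in_ch, n, 1, 1, rng, f"{name}.skip")

    def params(self):
        ps = [p for layer in self.layers for p in layer.params()]
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def forward(self, x, training: bool = False):
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        s = x if self.skip is None else self.skip.forward(x, training)
        return h + s

    def backward(self, gy):
        gs = gy if self.skip is None else self.skip.backward(gy)
        gh = gy
        for layer in reversed(self.layers):
            gh = layer.backward(gh)
        return gh + gs


class TCNStack:
    """``n_stacks`` passes over the dilation schedule, one block per dilation."""

    def __init__(self, in_ch: int, config: TCNConfig, rng: np.random.Generator,
                 name: str = "tcn"):
        self.blocks = []
        ch = in_ch
        for s in range(config.n_stacks):
            for d in config.dilations:
                self.blocks.append(ResidualBlock(ch, config, d, rng,
                                                 f"{name}.s{s}d{d}"))
                ch = config.n_filters

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x, training: bool = False):
        h = x
        for b in self.blocks:
            h = b.forward(h, training)
        return h

    def backward(self, gy):
        g = gy
        for b in reversed(self.blocks):
            g = b.backward(g)
        return g


class TCNEncoder:
    """Maps an input sequence to a latent state vector.

    The latent state is the feature vector of the final time step of the top
    residual stack — the causal summary of everything the encoder saw.

    Because the latent is a single causal output, inputs older than the
    stack's receptive field cannot influence it; the forward pass therefore
    trims each block's computation to the suffix the layers above still
    need.  This is an exact reformulation (identical latent and identical
    parameter gradients), not an approximation.
    """

    def __init__(self, in_ch: int, config: TCNConfig, rng: np.random.Generator,
                 name: str = "enc"):
        self.stack = TCNStack(in_ch, config, rng, name)
        # needed suffix length at each block boundary, top -> bottom:
        # one position at the top; each block (two convs) adds 2 (k-1) d
        k = config.kernel_size
        need = [1]
        for block in reversed(self.blocks):
            d = block.layers[0].d
            need.append(need[-1] + 2 * (k - 1) * d)
        self._need = need[::-1]  # [input_len, after block 1, ..., 1]
        self._keep = None

    @property
    def blocks(self):
        return self.stack.blocks

    def params(self):
        return self.stack.params()

    def forward(self, x, training: bool = False):
        if x.ndim != 3 or x.shape[1] < 1:
            raise ValueError("encoder input must be (batch, time>=1, channels)")
        T = x.shape[1]
        keep = [min(n, T) for n in self._need]
        self._keep = keep
        h = x[:, T - keep[0]:, :]
        for i, block in enumerate(self.blocks):
            h = block.forward(h, training)
            if h.shape[1] > keep[i + 1]:
                h = h[:, h.shape[1] - keep[i + 1]:, :]
        return h[:, -1, :]

    def backward(self, glatent):
        keep = self._keep
        B, C = glatent.shape
        g = glatent[:, None, :]
        for i in range(len(self.blocks) - 1, -1, -1):
            if g.shape[1] < keep[i]:
                pad = np.zeros((B, keep[i] - g.shape[1], g.shape[2]),
                               dtype=DTYPE)
                g = np.concatenate([pad, g], axis=1)
            g = self.blocks[i].backward(np.ascontiguousarray(g))
        return g


class TCNDecoder:
    """Expands a latent vector into ``f`` feature vectors.

    The latent state is repeated f times to form the decoder input sequence
    (non-autoregressive realization); a TCN stack then produces one feature
    vector per horizon step.
    """

    def __init__(self, config: TCNConfig, rng: np.random.Generator,
                 name: str = "dec"):
        self.stack = TCNStack(config.n_filters, config, rng, name)

    def params(self):
        return self.stack.params()

    def forward(self, latent, f: int, training: bool = False):
        if f < 1:
            raise ValueError("horizon f must be >= 1")
        rep = np.repeat(latent[:, None, :], f, axis=1)
        return self.stack.forward(np.ascontiguousarray(rep, dtype=DTYPE), training)

    def backward(self, gy):
        grep = self.stack.backward(gy)
        return grep.sum(axis=1)


class TimeDistributedDense:
    """Applies the same dense map to every temporal slice (features -> 1)."""

    def __init__(self, in_ch: int, rng: np.random.Generator, name: str = "head"):
        scale = np.sqrt(1.0 / in_ch)
        self.W = Param(rng.normal(0.0, scale, (in_ch, 1)), f"{name}.W")
        self.b = Param(np.zeros(1), f"{name}.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training: bool = False):
        self._x = x
        return (x @ self.W.value + self.b.value)[:, :, 0]

    def backward(self, gy):
        g3 = np.ascontiguousarray(gy, dtype=DTYPE)[:, :, None]
        B, T, _ = g3.shape
        self.W.grad += self._x.reshape(B * T, -1).T @ g3.reshape(B * T, 1)
        self.b.grad += g3.sum(axis=(0, 1))
        return (g3 * self.W.value[:, 0]).astype(DTYPE)


def flatten_params(params: list[Param]):
    """Re-home parameter values/grads into two contiguous buffers.

    Each Param's ``value``/``grad`` becomes a view into the shared buffer, so
    layers keep working unchanged while the optimizer updates one vector.
    """
    total = sum(p.value.size for p in params)
    buf = np.empty(total, dtype=DTYPE)
    gbuf = np.zeros(total, dtype=DTYPE)
    ofs = 0
    for p in params:
        n = p.value.size
        buf[ofs:ofs + n] = p.value.ravel()
        p.value = buf[ofs:ofs + n].reshape(p.value.shape)
        p.grad = gbuf[ofs:ofs + n].reshape(p.grad.shape)
        ofs += n
    return buf, gbuf


class Adam:
    """Adam optimizer over a list of :class:`Param` (single flat buffer)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.buf, self.gbuf = flatten_params(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros_like(self.buf)
        self.v = np.zeros_like(self.buf)
        self.t = 0

    def zero_grad(self):
        self.gbuf[...] = 0.0

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        m, v, g = self.m, self.v, self.gbuf
        m *= self.b1
        m += (1 - self.b1) * g
        v *= self.b2
        v += (1 - self.b2) * g * g
        self.buf -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
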