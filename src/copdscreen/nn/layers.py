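"""Building blocks of the classifier: Conv1D+BN+ReLU, SE gating, frequency
gate, attentive statistics pooling, dropout and linear heads."""
from __future__ import annotations

import numpy as np

from .autograd import Module, Parameter, Tensor, concat, conv1d, softmax


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1):
        self.dilation = dilation
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch, kernel), in_ch * kernel))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, time); running stats for eval."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(n_ch, dtype=np.float32))
        self.beta = Parameter(np.zeros(n_ch, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_ch, dtype=np.float32)
        self.running_var = np.ones(n_ch, dtype=np.float32)
        # running stats are seeded from the first batch instead of (0, 1):
        # with few optimizer steps per epoch an arbitrary init would dominate
        # eval-mode statistics for several epochs
        self._stats_initialized = False

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = 1.0 if not self._stats_initialized else self.momentum
            self._stats_initialized = True
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.ravel())
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.ravel())
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class SEBlock(Module):
    """Squeeze-and-excitation channel gate: temporal mean -> bottleneck ->
    sigmoid gate in (0,1), applied multiplicatively per channel."""

    def __init__(self, n_ch: int, rng: np.random.Generator, reduction: int = 16):
        hidden = max(1, n_ch // reduction)
        self.w1 = Parameter(_kaiming(rng, (n_ch, hidden), n_ch))
        self.b1 = Parameter(np.zeros(hidden, dtype=np.float32))
        self.w2 = Parameter(_kaiming(rng, (hidden, n_ch), hidden))
        self.b2 = Parameter(np.zeros(n_ch, dtype=np.float32))

    def gates(self, x: Tensor) -> Tensor:
        s = x.mean(axis=2)  # (B, C) squeeze
        h = (s @ self.w1 + self.b1).relu()
        return (h @ self.w2 + self.b2).sigmoid()  # (B, C) in (0,1)

    def __call__(self, x: Tensor) -> Tensor:
        g = self.gates(x)
        B, C = g.shape
        return x * g.reshape(B, C, 1)


class FreqGate(Module):
    """Learnable per-frequency-band multiplicative gate, 2*sigmoid(b) with
    b=0 at init so the gate starts as an exact identity."""

    def __init__(self, n_bands: int):
        self.logit = Parameter(np.zeros(n_bands, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        g = self.logit.sigmoid() * 2.0
        return x * g.reshape(1, -1, 1)


class AttentiveStatsPooling(Module):
    """Attention-weighted mean and standard deviation over time.

    A bottleneck network scores each frame; softmax over time yields weights
    alpha_t (nonnegative, summing to 1). Pooled vector is [mu; sigma] with
    mu = sum_t alpha_t h_t and sigma = sqrt(sum_t alpha_t (h_t - mu)^2)
    (the biased weighted std, exactly as the pooling statistic is defined).
    """

    def __init__(self, n_ch: int, rng: np.random.Generator, hidden: int = 128):
        self.att1 = Conv1d(n_ch, hidden, 1, rng)
        self.att2 = Conv1d(hidden, 1, 1, rng)

    def attention(self, h: Tensor) -> Tensor:
        scores = self.att2(self.att1(h).tanh())  # (B, 1, T)
        return softmax(scores, axis=2)

    def __call__(self, h: Tensor, alpha: Tensor | None = None):
        """Pool (B, C, T) -> (B, 2C); returns (pooled, alpha)."""
        if alpha is None:
            alpha = self.attention(h)
        mu = (h * alpha).sum(axis=2)  # (B, C)
        B, C = mu.shape
        var = (((h - mu.reshape(B, C, 1)) ** 2) * alpha).sum(axis=2)
        sigma = (var + 1e-10).sqrt()
        return concat([mu, sigma], axis=1), alpha


class GlobalAvgPooling(Module):
    def __call__(self, h: Tensor):
        return h.mean(axis=2), None


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Parameter(_kaiming(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Res2Conv(Module):
    """Multi-scale temporal convolution: channels split into `scales` groups;
    group i is convolved after adding the previous group's output (hierarchical
    residual connectivity), widening the receptive field within one block."""

    def __init__(self, n_ch: int, kernel: int, rng: np.random.Generator,
                 scales: int = 4, dilation: int = 1):
        if n_ch % scales != 0:
            raise ValueError("channels must divide evenly into scales")
        self.scales = scales
        self.width = n_ch // scales
        self.convs = [Conv1d(self.width, self.width, kernel, rng, dilation=dilation)
                      for _ in range(scales - 1)]

    def __call__(self, x: Tensor) -> Tensor:
        parts = [x.narrow(1, i * self.width, self.width) for i in range(self.scales)]
        out = [parts[0]]
        prev = None
        for i in range(1, self.scales):
            inp = parts[i] if prev is None else parts[i] + prev
            prev = self.convs[i - 1](inp).relu()
            out.append(prev)
        return concat(out, axis=1)
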