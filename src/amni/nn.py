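"""NumPy neural-network primitives with explicit backpropagation.

Each layer caches on ``forward`` exactly what its ``backward`` needs, and
``backward`` accumulates parameter gradients in-place while returning the
gradient with respect to the layer input.  Layers are dtype-polymorphic:
they compute in the dtype of their parameters (training uses float32;
float64 is used where tests compare against scalar-loop oracles).

Conventions
-----------
* Dense activations are ``(batch, features)``.
* Volumetric activations are channels-last ``(batch, H, W, D, channels)`` —
  the layout that keeps convolution im2col/col2im and batch-norm reductions
  contiguous in NumPy.
* 3-D convolutions are stride-1 with same-padding; max-pooling is 2x2x2
  stride 2 with floor division of odd spatial dims (no padding).
"""

from __future__ import annotations

import numpy as np

from .errors import ContractViolationError

__all__ = [
    "Param",
    "Linear",
    "ReLU",
    "Dropout",
    "Conv3d",
    "BatchNorm",
    "MaxPool3d",
    "Adam",
    "softmax",
    "glorot_uniform",
]


class Param:
    """A trainable tensor with an accumulated gradient.

    ``decay`` marks whether the parameter participates in weight decay
    (weights do; biases and batch-norm scale/shift do not).
    """

    __slots__ = ("name", "value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = "") -> None:
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.decay = bool(decay)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0


def glorot_uniform(
    shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator,
    dtype=np.float64,
) -> np.ndarray:
    """Fan-based uniform initialization on [-limit, limit], limit = sqrt(6/(fan_in+fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized by max subtraction."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ReLU:
    """Elementwise max(0, x)."""

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dropout:
    """Inverted dropout: active only in train mode, identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ContractViolationError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        if mode != "train" or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Linear:
    """Affine map y = x W + b."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        dtype=np.float64,
        bias: bool = True,
        name: str = "linear",
    ) -> None:
        self.W = Param(
            glorot_uniform((d_in, d_out), d_in, d_out, rng, dtype),
            name=f"{name}.W",
        )
        self.b = (
            Param(np.zeros(d_out, dtype=dtype), decay=False, name=f"{name}.b")
            if bias
            else None
        )

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        if x.shape[-1] != self.W.value.shape[0]:
            raise ContractViolationError(
                f"linear layer expects input width {self.W.value.shape[0]}, "
                f"got {x.shape[-1]}"
            )
        self._x = x
        out = x @ self.W.value
        if self.b is not None:
            out = out + self.b.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        if self.b is not None:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])


class Conv3d:
    """Stride-1 3-D convolution with same-padding, via im2col + one GEMM.

    Input/output layout is channels-last (batch, H, W, D, channels);
    spatial size is preserved (padding = (k-1)//2, odd k).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
        name: str = "conv",
    ) -> None:
        if kernel_size % 2 != 1:
            raise ContractViolationError("kernel size must be odd for same-padding")
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.k = int(kernel_size)
        self.pad = (self.k - 1) // 2
        rng = rng if rng is not None else np.random.default_rng(0)
        taps = self.k**3
        self.W = Param(
            glorot_uniform(
                (out_channels, in_channels, self.k, self.k, self.k),
                in_channels * taps,
                out_channels * taps,
                rng,
                dtype,
            ),
            name=f"{name}.W",
        )
        self.b = Param(np.zeros(out_channels, dtype=dtype), decay=False, name=f"{name}.b")

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        if x.ndim != 5 or x.shape[-1] != self.in_channels:
            raise ContractViolationError(
                f"conv expects (B, H, W, D, {self.in_channels}), got {x.shape}"
            )
        batch, h, w, d, _ = x.shape
        if min(h, w, d) < self.k:
            raise ContractViolationError(
                f"spatial dims {x.shape[1:4]} smaller than kernel {self.k}"
            )
        p, k = self.pad, self.k
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        # windows over the spatial axes: (B, H, W, D, C, k, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
        cols = win.reshape(batch * h * w * d, self.in_channels * k**3)
        self._cols = cols
        self._in_shape = x.shape
        w_mat = self.W.value.reshape(self.out_channels, -1)
        out = cols @ w_mat.T + self.b.value
        return out.reshape(batch, h, w, d, self.out_channels)

    def backward(self, grad: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        batch, h, w, d, _ = self._in_shape
        k, p = self.k, self.pad
        g = grad.reshape(-1, self.out_channels)
        self.W.grad += (g.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=0)
        self._cols = None
        if not need_input_grad:
            return None
        # input gradient = correlation of the padded output gradient with the
        # spatially flipped, channel-transposed kernel — one gather + one GEMM
        gp = np.pad(grad, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, (k, k, k), axis=(1, 2, 3))
        gcols = gwin.reshape(batch * h * w * d, self.out_channels * k**3)
        w_t = np.ascontiguousarray(
            self.W.value[:, :, ::-1, ::-1, ::-1].transpose(0, 2, 3, 4, 1)
        ).reshape(self.out_channels * k**3, self.in_channels)
        return (gcols @ w_t).reshape(batch, h, w, d, self.in_channels)

    def params(self) -> list[Param]:
        return [self.W, self.b]


class BatchNorm:
    """Batch normalization over all axes except the trailing channel axis.

    Train mode normalizes with batch statistics and updates running moments
    (momentum 0.1, unbiased variance for the running estimate, biased for
    normalization); eval mode uses the running moments.
    """

    def __init__(
        self,
        channels: int,
        eps: float = 1e-5,
        momentum: float = 0.1,
        dtype=np.float64,
        name: str = "bn",
    ) -> None:
        self.channels = int(channels)
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Param(np.ones(channels, dtype=dtype), decay=False, name=f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), decay=False, name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        if x.ndim < 2 or x.shape[-1] != self.channels:
            raise ContractViolationError(
                f"batch-norm expects trailing channel axis of size "
                f"{self.channels}, got {x.shape}"
            )
        axes = tuple(range(x.ndim - 1))
        if mode == "train":
            n = x.size // self.channels
            if n < 2:
                raise ContractViolationError(
                    "batch normalization needs >= 2 values per channel in train mode"
                )
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var * n / (n - 1)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std, n)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
            self._cache = None
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise ContractViolationError("batch-norm backward requires a train-mode forward")
        xhat, inv_std, n = self._cache
        axes = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value
        sum_dxhat = dxhat.sum(axis=axes)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes)
        return (inv_std / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class MaxPool3d:
    """2x2x2 max pooling with stride 2; trailing odd slices are dropped.

    Channels-last layout (B, H, W, D, C).
    """

    def __init__(self, size: int = 2) -> None:
        if size != 2:
            raise ContractViolationError("only 2x2x2 stride-2 pooling is supported")
        self.size = 2

    def forward(self, x: np.ndarray, mode: str = "train") -> np.ndarray:
        batch, h, w, d, ch = x.shape
        h2, w2, d2 = h // 2, w // 2, d // 2
        if min(h2, w2, d2) < 1:
            raise ContractViolationError(
                f"spatial dims {x.shape[1:4]} too small for 2x2x2 pooling"
            )
        windows = np.ascontiguousarray(
            x[:, : 2 * h2, : 2 * w2, : 2 * d2, :]
            .reshape(batch, h2, 2, w2, 2, d2, 2, ch)
            .transpose(0, 1, 3, 5, 2, 4, 6, 7)
        ).reshape(batch, h2, w2, d2, 8, ch)
        self._arg = windows.argmax(axis=4)
        self._in_shape = x.shape
        return np.take_along_axis(windows, self._arg[:, :, :, :, None, :], axis=4)[
            :, :, :, :, 0, :
        ]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        batch, h2, w2, d2, ch = grad.shape
        windows = np.zeros((batch, h2, w2, d2, 8, ch), dtype=grad.dtype)
        np.put_along_axis(
            windows, self._arg[:, :, :, :, None, :], grad[:, :, :, :, None, :], axis=4
        )
        block = (
            windows.reshape(batch, h2, w2, d2, 2, 2, 2, ch)
            .transpose(0, 1, 4, 2, 5, 3, 6, 7)
            .reshape(batch, 2 * h2, 2 * w2, 2 * d2, ch)
        )
        out = np.zeros(self._in_shape, dtype=grad.dtype)
        out[:, : 2 * h2, : 2 * w2, : 2 * d2, :] = block
        return out


class Adam:
    """Adam with optional decoupled-from-BN L2 weight decay.

    Decay is added to the gradient (classic Adam + L2) for every parameter
    whose ``decay`` flag is set; biases and batch-norm parameters opt out.
    """

    def __init__(
        self,
        params: list[Param],
        learning_rate: float = 1e-4,
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr = float(learning_rate)
        self.weight_decay = float(weight_decay)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
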