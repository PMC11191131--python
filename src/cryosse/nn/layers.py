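"""Layer primitives with explicit forward/backward passes.

Convolutions are evaluated as 27 shifted GEMMs (one per kernel offset)
instead of an im2col patch matrix; this keeps peak memory at one padded copy
of the activation regardless of channel count.  The stride-2 transpose
convolution exploits output parity: an output voxel of parity p along an
axis receives contributions only from kernel taps of matching parity, so the
layer decomposes into 8 small convolutions on the input grid, with the same
FLOP count as a stride-1 convolution of the *input* size.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "MaxPool2",
    "ReLU",
    "Dropout",
]


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad", "regularizable")

    def __init__(self, data: np.ndarray, regularizable: bool = False):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.regularizable = regularizable

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def parameters(self) -> list[Parameter]:
        return []


# three kernel offsets per axis: (kernel index, padded-input offset)
_OFFSETS = ((0, 0), (1, 1), (2, 2))


class Conv3d(Layer):
    """3×3×3 (or 1×1×1) same-padding convolution with bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
    ):
        if kernel_size not in (1, 3):
            raise ValueError("kernel_size must be 1 or 3")
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel_size
        rng = rng or np.random.default_rng()
        fan_in = kernel_size**3 * in_channels
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, *(kernel_size,) * 3)),
            regularizable=True,
        )
        self.bias = Parameter(np.zeros(out_channels))
        self._cache: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cin, d, h, w = x.shape
        n = d * h * w
        if self.k == 1:
            wmat = self.weight.data.reshape(self.cout, self.cin)
            y = wmat @ x.reshape(cin, n)
            self._cache = x
        else:
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
            y = np.zeros((self.cout, n), dtype=np.float32)
            wd = self.weight.data
            for ka, oa in _OFFSETS:
                for kb, ob in _OFFSETS:
                    for kc, oc in _OFFSETS:
                        xs = xp[:, oa : oa + d, ob : ob + h, oc : oc + w].reshape(
                            cin, n
                        )
                        y += wd[:, :, ka, kb, kc] @ xs
            self._cache = xp
        y = y.reshape(self.cout, d, h, w) + self.bias.data[:, None, None, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cout, d, h, w = dy.shape
        n = d * h * w
        dyf = np.ascontiguousarray(dy.reshape(cout, n))
        self.bias.grad += dyf.sum(axis=1)
        if self.k == 1:
            x = self._cache
            self.weight.grad += (dyf @ x.reshape(self.cin, n).T).reshape(
                self.weight.data.shape
            )
            dx = (self.weight.data.reshape(cout, self.cin).T @ dyf).reshape(
                self.cin, d, h, w
            )
            return dx
        xp = self._cache
        dxp = np.zeros_like(xp)
        wd = self.weight.data
        wg = self.weight.grad
        for ka, oa in _OFFSETS:
            for kb, ob in _OFFSETS:
                for kc, oc in _OFFSETS:
                    xs = xp[:, oa : oa + d, ob : ob + h, oc : oc + w].reshape(
                        self.cin, n
                    )
                    wg[:, :, ka, kb, kc] += dyf @ xs.T
                    dxp[:, oa : oa + d, ob : ob + h, oc : oc + w] += (
                        wd[:, :, ka, kb, kc].T @ dyf
                    ).reshape(self.cin, d, h, w)
        return dxp[:, 1:-1, 1:-1, 1:-1]


# parity taps for stride-2 kernel-3 transpose convolution:
# output index o = 2j + parity; contributing input index and kernel tap
_TAPS = {0: ((1, 0),), 1: ((0, 0), (2, 1))}  # parity -> ((kernel idx, input offset), ...)


class ConvTranspose3d(Layer):
    """3×3×3 transpose convolution with stride 2; output is 2× each dim."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator | None = None,
    ):
        self.cin = in_channels
        self.cout = out_channels
        rng = rng or np.random.default_rng()
        fan_in = 27 * in_channels / 8.0  # each output sees ~27/8 taps on average
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, 3, 3, 3)),
            regularizable=True,
        )
        self.bias = Parameter(np.zeros(out_channels))
        self._cache: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        cin, d, h, w = x.shape
        n = d * h * w
        xp = np.pad(x, ((0, 0), (0, 1), (0, 1), (0, 1)))
        y = np.empty((self.cout, 2 * d, 2 * h, 2 * w), dtype=np.float32)
        wd = self.weight.data
        for pa in (0, 1):
            for pb in (0, 1):
                for pc in (0, 1):
                    acc = np.zeros((self.cout, n), dtype=np.float32)
                    for ka, oa in _TAPS[pa]:
                        for kb, ob in _TAPS[pb]:
                            for kc, oc in _TAPS[pc]:
                                xs = xp[
                                    :, oa : oa + d, ob : ob + h, oc : oc + w
                                ].reshape(cin, n)
                                acc += wd[:, :, ka, kb, kc] @ xs
                    y[:, pa::2, pb::2, pc::2] = acc.reshape(self.cout, d, h, w)
        y += self.bias.data[:, None, None, None]
        self._cache = xp
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._cache
        cin = self.cin
        d, h, w = xp.shape[1] - 1, xp.shape[2] - 1, xp.shape[3] - 1
        n = d * h * w
        self.bias.grad += dy.sum(axis=(1, 2, 3))
        dxp = np.zeros_like(xp)
        wd = self.weight.data
        wg = self.weight.grad
        for pa in (0, 1):
            for pb in (0, 1):
                for pc in (0, 1):
                    dyf = np.ascontiguousarray(
                        dy[:, pa::2, pb::2, pc::2].reshape(self.cout, n)
                    )
                    for ka, oa in _TAPS[pa]:
                        for kb, ob in _TAPS[pb]:
                            for kc, oc in _TAPS[pc]:
                                xs = xp[
                                    :, oa : oa + d, ob : ob + h, oc : oc + w
                                ].reshape(cin, n)
                                wg[:, :, ka, kb, kc] += dyf @ xs.T
                                dxp[:, oa : oa + d, ob : ob + h, oc : oc + w] += (
                                    wd[:, :, ka, kb, kc].T @ dyf
                                ).reshape(cin, d, h, w)
        return dxp[:, :d, :h, :w]


class BatchNorm3d(Layer):
    """Per-channel normalization over the spatial axes (batch size 1).

    With whole-volume batches of size 1 this is per-volume (instance)
    normalization.  Inference therefore also normalizes with the current
    volume's own statistics: running averages accumulated over a handful of
    heterogeneous chain volumes cannot stand in for per-volume statistics,
    and using them creates a large train/inference mismatch.  Running
    statistics are still tracked and checkpointed for reference.
    """

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.9):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mean = x.mean(axis=(1, 2, 3))
        var = x.var(axis=(1, 2, 3))
        if training:
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None, None]) * inv_std[:, None, None, None]
        y = (
            self.gamma.data[:, None, None, None] * xhat
            + self.beta.data[:, None, None, None]
        )
        if training:
            self._cache = (xhat, inv_std)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dy[0].size
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        g = self.gamma.data[:, None, None, None] * inv_std[:, None, None, None]
        sum_dy = dy.sum(axis=(1, 2, 3), keepdims=True)
        sum_dy_xhat = (dy * xhat).sum(axis=(1, 2, 3), keepdims=True)
        dx = g * (dy - sum_dy / n - xhat * sum_dy_xhat / n)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2×2×2 max pooling with stride 2; input dims must be even."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even dims, got {x.shape[1:]}")
        blocks = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        self._argmax = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(blocks, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, d, h, w = self._in_shape
        blocks = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(blocks, self._argmax[..., None], dy[..., None], axis=-1)
        return (
            blocks.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate is 0."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._mask = None

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode requires an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask
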