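"""The 5-layer 3D U-Net and its combined weighted-CE + dice loss.

The network follows the original 3D U-Net layout truncated to two pooling
levels: a contracting path of two layers, a bottleneck, and an expanding
path of two layers.  Each layer is two (3×3×3 convolution → batch norm →
ReLU) blocks; the channel count doubles once per layer on the second
convolution (32→64, 64→128, 128→256 at base width 32).  Down layers end
with dropout and a 2×2×2 stride-2 max pool; up layers start with dropout
and a 3×3×3 stride-2 transpose convolution, concatenate the same-scale
skip, and finish with two conv blocks.  A final 1×1×1 convolution maps to
the three class channels.  At the default configuration the network has
6,142,723 trainable parameters.

The loss couples a per-voxel class-weighted categorical cross-entropy
(weights inversely proportional to class frequency, normalized to sum to 3)
with a soft-dice complement averaged over the three classes; both terms
carry unit weight by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labeling import VoxelLabelGrid
from .nn import (
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    Dropout,
    MaxPool2,
    Parameter,
    ReLU,
)

__all__ = [
    "NetworkConfig",
    "LossConfig",
    "UNet3D",
    "ShapeError",
    "build_unet",
    "count_parameters",
    "class_weights",
    "dice_coefficient",
    "combined_loss",
    "softmax_channels",
    "loss_and_gradient",
]

PUBLISHED_PARAMETER_TOTAL = 6_142_723


class ShapeError(ValueError):
    """Input dims incompatible with the two stride-2 poolings."""


@dataclass
class NetworkConfig:
    """Channel schedule and regularization of the segmentation network.

    The default (base_width 32, one doubling per level, mirrored decoder)
    resolves to the schedule whose trainable-parameter total equals the
    published count; see docs/methods.md for the schedule search table.
    """

    base_width: int = 32
    doubling_policy: str = "per_level"     # or "per_convolution"
    decoder_width_policy: str = "mirror"   # or "halve"
    dropout_rate: float = 0.5
    l2_coefficient: float = 1e-4
    n_classes: int = 3

    def resolve_schedule(self) -> dict:
        """Concrete channel widths for every convolution in the network."""
        w = self.base_width
        if self.doubling_policy == "per_level":
            enc = [(1, w, 2 * w), (2 * w, 2 * w, 4 * w), (4 * w, 4 * w, 8 * w)]
        elif self.doubling_policy == "per_convolution":
            enc = [(1, w, 2 * w), (2 * w, 4 * w, 8 * w), (8 * w, 16 * w, 32 * w)]
        else:
            raise ValueError(f"unknown doubling_policy {self.doubling_policy!r}")
        skip1, skip2 = enc[0][2], enc[1][2]
        bott = enc[2][2]
        if self.decoder_width_policy == "mirror":
            t1 = bott // 2
            cat1 = t1 + skip2
            dec1 = (cat1, cat1, cat1 // 2)
            t2 = dec1[2]
            cat2 = t2 + skip1
            dec2 = (cat2, skip1, skip1)
        elif self.decoder_width_policy == "halve":
            t1 = bott // 2
            dec1 = (t1 + skip2, t1, t1 // 2)
            t2 = dec1[2]
            dec2 = (t2 + skip1, t2 // 2, t2 // 2)
        else:
            raise ValueError(
                f"unknown decoder_width_policy {self.decoder_width_policy!r}"
            )
        return {
            "encoder": enc,
            "tconv": (t1, t2),
            "decoder": (dec1, dec2),
            "final_in": dec2[2],
        }


@dataclass
class LossConfig:
    """Weights and constants of the combined segmentation loss."""

    class_weights: np.ndarray = field(default_factory=lambda: np.ones(3))
    dice_smooth: float = 1.0
    lambda_ce: float = 1.0
    lambda_dice: float = 1.0

    def __post_init__(self) -> None:
        self.class_weights = np.asarray(self.class_weights, dtype=np.float64).reshape(3)
        if np.any(self.class_weights <= 0):
            raise ValueError("class weights must be positive")
        if self.dice_smooth <= 0:
            raise ValueError("dice_smooth must be positive")
        if self.lambda_ce < 0 or self.lambda_dice < 0:
            raise ValueError("loss mixing weights must be non-negative")


class _ConvBlock:
    """conv → batch norm → ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv3d(cin, cout, 3, rng=rng)
        self.bn = BatchNorm3d(cout)
        self.relu = ReLU()

    def forward(self, x, training):
        return self.relu.forward(
            self.bn.forward(self.conv.forward(x, training), training), training
        )

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    def parameters(self):
        return self.conv.parameters() + self.bn.parameters()


class UNet3D:
    """Fully convolutional 5-layer 3D U-Net over (1, D, H, W) inputs.

    D, H, W must each be a multiple of 4 (two stride-2 poolings); padding to
    that stride is the caller's job (see train_predict.pad_to_stride).
    """

    STRIDE = 4

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(seed)
        s = self.config.resolve_schedule()
        (e1i, e1m, e1o), (e2i, e2m, e2o), (ebi, ebm, ebo) = s["encoder"]
        t1, t2 = s["tconv"]
        (d1i, d1m, d1o), (d2i, d2m, d2o) = s["decoder"]
        dr = self.config.dropout_rate

        self.enc1 = [_ConvBlock(e1i, e1m, rng), _ConvBlock(e1m, e1o, rng)]
        self.drop1 = Dropout(dr)
        self.pool1 = MaxPool2()
        self.enc2 = [_ConvBlock(e2i, e2m, rng), _ConvBlock(e2m, e2o, rng)]
        self.drop2 = Dropout(dr)
        self.pool2 = MaxPool2()
        self.bott = [_ConvBlock(ebi, ebm, rng), _ConvBlock(ebm, ebo, rng)]
        self.drop3 = Dropout(dr)
        self.tconv1 = ConvTranspose3d(ebo, t1, rng=rng)
        self.dec1 = [_ConvBlock(d1i, d1m, rng), _ConvBlock(d1m, d1o, rng)]
        self.drop4 = Dropout(dr)
        self.tconv2 = ConvTranspose3d(d1o, t2, rng=rng)
        self.dec2 = [_ConvBlock(d2i, d2m, rng), _ConvBlock(d2m, d2o, rng)]
        self.final = Conv3d(d2o, self.config.n_classes, 1, rng=rng)
        self._skip_channels = (e1o, e2o)

    # -- plumbing ---------------------------------------------------------

    def _blocks(self):
        return [
            *self.enc1,
            *self.enc2,
            *self.bott,
            *self.dec1,
            *self.dec2,
        ]

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for block in self._blocks():
            params.extend(block.parameters())
        params.extend(self.tconv1.parameters())
        params.extend(self.tconv2.parameters())
        params.extend(self.final.parameters())
        return params

    # -- forward / backward -----------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Logits of shape (n_classes, D, H, W) for input (1, D, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[0] != 1:
            raise ShapeError(f"expected input (1, D, H, W), got {x.shape}")
        if any(dim % self.STRIDE for dim in x.shape[1:]):
            raise ShapeError(
                f"input dims {x.shape[1:]} must be multiples of {self.STRIDE}; "
                "pad the map first"
            )
        h = x
        for block in self.enc1:
            h = block.forward(h, training)
        skip1 = h
        h = self.pool1.forward(self.drop1.forward(h, training, rng), training)
        for block in self.enc2:
            h = block.forward(h, training)
        skip2 = h
        h = self.pool2.forward(self.drop2.forward(h, training, rng), training)
        for block in self.bott:
            h = block.forward(h, training)
        h = self.tconv1.forward(self.drop3.forward(h, training, rng), training)
        h = np.concatenate([h, skip2], axis=0)
        for block in self.dec1:
            h = block.forward(h, training)
        h = self.tconv2.forward(self.drop4.forward(h, training, rng), training)
        h = np.concatenate([h, skip1], axis=0)
        for block in self.dec2:
            h = block.forward(h, training)
        return self.final.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.final.backward(dlogits)
        for block in reversed(self.dec2):
            d = block.backward(d)
        t2 = self.tconv2.cout
        d_up, d_skip1 = d[:t2], d[t2:]
        d = self.drop4.backward(self.tconv2.backward(d_up))
        for block in reversed(self.dec1):
            d = block.backward(d)
        t1 = self.tconv1.cout
        d_up, d_skip2 = d[:t1], d[t1:]
        d = self.drop3.backward(self.tconv1.backward(d_up))
        for block in reversed(self.bott):
            d = block.backward(d)
        d = self.drop2.backward(self.pool2.backward(d)) + d_skip2
        for block in reversed(self.enc2):
            d = block.backward(d)
        d = self.drop1.backward(self.pool1.backward(d)) + d_skip1
        for block in reversed(self.enc1):
            d = block.backward(d)

    # -- persistence ------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i}"] = p.data
        bns = [
            b.bn
            for b in self._blocks()
        ]
        for i, bn in enumerate(bns):
            state[f"bn_{i}_mean"] = bn.running_mean
            state[f"bn_{i}_var"] = bn.running_var
        return state

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as data:
            for i, p in enumerate(self.parameters()):
                arr = data[f"param_{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError(
                        f"checkpoint shape mismatch on param {i}: "
                        f"{arr.shape} vs {p.data.shape}"
                    )
                p.data[...] = arr
            bns = [b.bn for b in self._blocks()]
            for i, bn in enumerate(bns):
                bn.running_mean[...] = data[f"bn_{i}_mean"]
                bn.running_var[...] = data[f"bn_{i}_var"]


def build_unet(config: NetworkConfig | None = None, seed: int = 0) -> UNet3D:
    return UNet3D(config=config, seed=seed)


def count_parameters(network: UNet3D) -> int:
    """Total trainable scalars: conv kernels, biases, BN scale and offset.

    Batch-norm running statistics are not trainable and are excluded.
    """
    return int(sum(p.size for p in network.parameters()))


def class_weights(frequencies: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Class weights inversely proportional to voxel fractions, summing to 3."""
    f = np.asarray(frequencies, dtype=np.float64).reshape(3)
    if np.any(f < floor):
        import logging

        logging.getLogger(__name__).warning(
            "class frequency below %g clipped: %s", floor, f
        )
    f = np.clip(f, floor, None)
    inv = 1.0 / f
    return 3.0 * inv / inv.sum()


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Softmax over the leading (class) axis."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def _one_hot(truth: VoxelLabelGrid | np.ndarray, n_classes: int = 3) -> np.ndarray:
    labels = truth.labels if isinstance(truth, VoxelLabelGrid) else np.asarray(truth)
    onehot = np.zeros((n_classes, *labels.shape), dtype=np.float64)
    for c in range(n_classes):
        onehot[c] = labels == c
    return onehot


def dice_coefficient(
    pred: np.ndarray,
    truth: VoxelLabelGrid | np.ndarray,
    smooth: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Soft dice per class and the 3-class mean.

    ``pred`` holds per-voxel class probabilities, class axis first.  For
    class c with one-hot truth t: (2 Σ p_c t_c + ε) / (Σ p_c + Σ t_c + ε).
    """
    onehot = _one_hot(truth, pred.shape[0])
    p = pred.reshape(pred.shape[0], -1).astype(np.float64)
    t = onehot.reshape(onehot.shape[0], -1)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    per_class = (2.0 * inter + smooth) / (denom + smooth)
    return per_class, float(per_class.mean())


def combined_loss(
    pred: np.ndarray,
    truth: VoxelLabelGrid | np.ndarray,
    loss_config: LossConfig | None = None,
) -> float:
    """λ_CE · weighted cross-entropy + λ_dice · (1 − mean dice).

    ``pred`` are per-voxel class probabilities (clipped to avoid log 0).
    """
    cfg = loss_config or LossConfig()
    onehot = _one_hot(truth, pred.shape[0])
    p = np.clip(pred.astype(np.float64), 1e-7, 1.0 - 1e-7)
    w = cfg.class_weights[:, None]
    pf = p.reshape(p.shape[0], -1)
    tf = onehot.reshape(onehot.shape[0], -1)
    ce = float(-(w * tf * np.log(pf)).sum() / tf.shape[1])
    _, mean_dice = dice_coefficient(pred, truth, cfg.dice_smooth)
    return cfg.lambda_ce * ce + cfg.lambda_dice * (1.0 - mean_dice)


def loss_and_gradient(
    logits: np.ndarray,
    truth: VoxelLabelGrid | np.ndarray,
    loss_config: LossConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Combined loss and its analytic gradient with respect to the logits."""
    cfg = loss_config or LossConfig()
    probs = softmax_channels(logits.astype(np.float64))
    onehot = _one_hot(truth, logits.shape[0])
    n = onehot[0].size
    w = cfg.class_weights.reshape(3, 1, 1, 1)
    p = np.clip(probs, 1e-7, 1.0 - 1e-7)
    ce = float(-(w * onehot * np.log(p)).sum() / n)
    per_class, mean_dice = dice_coefficient(probs, truth, cfg.dice_smooth)
    loss = cfg.lambda_ce * ce + cfg.lambda_dice * (1.0 - mean_dice)

    # CE gradient through softmax: (w_t / n) (p - onehot) per voxel
    wt = (w * onehot).sum(axis=0, keepdims=True)
    dlogits = cfg.lambda_ce * wt * (probs - onehot) / n

    if cfg.lambda_dice > 0:
        # d(1 - mean dice)/dp_c(v) = -(1/3) (2 t_c(v) B_c - A_c) / B_c^2
        pf = probs.reshape(3, -1)
        tf = onehot.reshape(3, -1)
        inter = (pf * tf).sum(axis=1)
        denom = pf.sum(axis=1) + tf.sum(axis=1)
        a = 2.0 * inter + cfg.dice_smooth
        b = denom + cfg.dice_smooth
        dp = -(2.0 * onehot * b.reshape(3, 1, 1, 1) - a.reshape(3, 1, 1, 1)) / (
            3.0 * b.reshape(3, 1, 1, 1) ** 2
        )
        # chain through softmax
        dot = (dp * probs).sum(axis=0, keepdims=True)
        dlogits = dlogits + cfg.lambda_dice * probs * (dp - dot)
    return loss, dlogits.astype(np.float32)
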