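"""Training on labeled chain volumes and whole-chain inference.

Maps are normalized per chain (z-score) before entering the network; inputs
are zero-padded up to the next multiple of 4 so two stride-2 poolings divide
evenly, and predictions are cropped back to the original grid.  Training
iterates epochs × shuffled chains at batch size 1 with Adam and the combined
weighted-CE + dice loss; one seed controls weight initialization, shuffling
and dropout, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DensityMap
from .labeling import VoxelLabelGrid, class_frequencies
from .model import (
    LossConfig,
    UNet3D,
    class_weights,
    loss_and_gradient,
    softmax_channels,
)
from .nn import Adam

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "SegmentationResult",
    "pad_to_stride",
    "unpad",
    "train",
    "predict_chain",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the training loop (defaults as published)."""

    learning_rate: float = 0.001
    batch_size: int = 1
    epochs: int = 40
    dropout_rate: float = 0.5
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported (whole-chain volumes)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class SegmentationResult:
    """Per-voxel class probabilities and their argmax labels."""

    probabilities: np.ndarray  # (3, nx, ny, nz), aligned to the input map
    labels: VoxelLabelGrid

    def __post_init__(self) -> None:
        assert self.probabilities.shape[1:] == self.labels.shape


@dataclass
class CropRecord:
    original_shape: tuple[int, int, int]


def pad_to_stride(
    density_map: DensityMap, stride: int = 4
) -> tuple[DensityMap, CropRecord]:
    """Zero-pad each dim up to the next multiple of ``stride``."""
    shape = np.array(density_map.shape)
    target = ((shape + stride - 1) // stride) * stride
    pad = target - shape
    values = np.pad(
        density_map.values, [(0, int(p)) for p in pad], mode="constant"
    )
    padded = DensityMap(
        values=values,
        voxel_size=density_map.voxel_size,
        origin=density_map.origin,
    )
    return padded, CropRecord(original_shape=tuple(int(s) for s in shape))


def unpad(values: np.ndarray, crop: CropRecord) -> np.ndarray:
    """Crop the trailing padding introduced by :func:`pad_to_stride`."""
    sx, sy, sz = crop.original_shape
    return values[..., :sx, :sy, :sz]


def _normalize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values, dtype=np.float32)
    return ((values - values.mean()) / sd).astype(np.float32)


def train(
    pairs: list[tuple[DensityMap, VoxelLabelGrid]],
    network: UNet3D,
    training_config: TrainingConfig | None = None,
    loss_config: LossConfig | None = None,
) -> tuple[UNet3D, list[float]]:
    """Train the network in place; returns it with the per-epoch loss log.

    Class weights, unless given explicitly in ``loss_config``, are computed
    from the voxel class frequencies of the whole training set.
    """
    if not pairs:
        raise ValueError("training requires at least one (map, labels) pair")
    cfg = training_config or TrainingConfig()
    if loss_config is None:
        freqs = class_frequencies([labels for _, labels in pairs])
        loss_config = LossConfig(class_weights=class_weights(freqs))
    rng = np.random.default_rng(cfg.seed)

    prepared = []
    for density_map, labels in pairs:
        if density_map.shape != labels.shape:
            raise ValueError(
                f"map shape {density_map.shape} != label shape {labels.shape}"
            )
        padded, crop = pad_to_stride(density_map, network.STRIDE)
        padded_labels = np.pad(
            labels.labels,
            [
                (0, padded.shape[i] - labels.shape[i])
                for i in range(3)
            ],
            mode="constant",
        )
        prepared.append((_normalize(padded.values)[None], padded_labels))

    optimizer = Adam(
        network.parameters(),
        learning_rate=cfg.learning_rate,
        l2_coefficient=network.config.l2_coefficient,
    )
    epoch_losses: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(prepared))
        losses = []
        t0 = time.time()
        for idx in order:
            x, labels = prepared[idx]
            optimizer.zero_grad()
            logits = network.forward(x, training=True, rng=rng)
            loss, dlogits = loss_and_gradient(logits, labels, loss_config)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, chain {idx}"
                )
            network.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        epoch_losses.append(float(np.mean(losses)))
        logger.info(
            "epoch %d/%d: loss %.4f (%.1f s)",
            epoch + 1,
            cfg.epochs,
            epoch_losses[-1],
            time.time() - t0,
        )
    return network, epoch_losses


def predict_chain(density_map: DensityMap, network: UNet3D) -> SegmentationResult:
    """Segment a whole chain map of any size (padded internally)."""
    padded, crop = pad_to_stride(density_map, network.STRIDE)
    x = _normalize(padded.values)[None]
    logits = network.forward(x, training=False)
    probs = unpad(softmax_channels(logits), crop)
    labels = VoxelLabelGrid(
        labels=probs.argmax(axis=0).astype(np.int8),
        voxel_size=density_map.voxel_size,
        origin=density_map.origin,
    )
    return SegmentationResult(probabilities=probs, labels=labels)
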