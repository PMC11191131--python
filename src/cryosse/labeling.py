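"""Ground-truth voxel labels from annotated chains.

STRIDE codes collapse to three classes: H/G/I count as helix, B/b/E as
β-sheet, everything else (turns, coil, unknown codes) as background.  A voxel
is labeled with a class when its center lies within a closed 3 Å sphere of a
Cα of that class; helix takes precedence over sheet wherever both apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import AtomicChain, DensityMap, SSClass

logger = logging.getLogger(__name__)

__all__ = ["VoxelLabelGrid", "ss_class_of_code", "label_voxels", "class_frequencies"]

_HELIX_CODES = frozenset("HGI")
_SHEET_CODES = frozenset({"B", "b", "E"})


@dataclass
class VoxelLabelGrid:
    """Per-voxel class grid aligned with a :class:`DensityMap`.

    Encoding: background=0, helix=1, sheet=2.
    """

    labels: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if self.labels.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {self.labels.shape}")
        if not np.isin(self.labels, (0, 1, 2)).all():
            raise ValueError("labels must be in {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def to_density_map(self) -> DensityMap:
        """Express the labels as a float map (for MRC serialization)."""
        return DensityMap(
            values=self.labels.astype(np.float32),
            voxel_size=self.voxel_size,
            origin=self.origin,
        )

    def class_mask(self, ss_class: SSClass) -> np.ndarray:
        return self.labels == int(ss_class)


def ss_class_of_code(stride_code: str) -> SSClass:
    """Collapse a one-character STRIDE code to the three-class scheme."""
    if stride_code in _HELIX_CODES:
        return SSClass.HELIX
    if stride_code in _SHEET_CODES:
        return SSClass.SHEET
    return SSClass.BACKGROUND


def label_voxels(
    chain: AtomicChain,
    grid_template: DensityMap,
    radius: float = 3.0,
) -> VoxelLabelGrid:
    """Label voxels within ``radius`` of helix/sheet Cα atoms.

    The sphere is closed (boundary voxels at exactly ``radius`` are labeled)
    and distances are measured to voxel centers.  Helix wins any conflict.
    """
    labels = np.zeros(grid_template.shape, dtype=np.int8)
    if len(chain) == 0:
        logger.warning("label_voxels called with an empty chain: all background")
        return VoxelLabelGrid(
            labels=labels,
            voxel_size=grid_template.voxel_size,
            origin=grid_template.origin,
        )
    centers = grid_template.voxel_centers().reshape(-1, 3)
    # sheet first so that helix overwrites any overlap
    for ss_class in (SSClass.SHEET, SSClass.HELIX):
        cas = chain.ca_positions(ss_class)
        if cas.size == 0:
            continue
        tree = cKDTree(cas)
        dist, _ = tree.query(centers, k=1, distance_upper_bound=radius * 1.001)
        within = (dist <= radius).reshape(grid_template.shape)
        labels[within] = int(ss_class)
    return VoxelLabelGrid(
        labels=labels,
        voxel_size=grid_template.voxel_size,
        origin=grid_template.origin,
    )


def class_frequencies(
    grids: VoxelLabelGrid | Iterable[VoxelLabelGrid],
) -> np.ndarray:
    """Per-class voxel fractions (background, helix, sheet) across grids."""
    if isinstance(grids, VoxelLabelGrid):
        grids = [grids]
    grids = list(grids)
    if not grids:
        raise ValueError("class_frequencies needs at least one label grid")
    counts = np.zeros(3, dtype=np.int64)
    for grid in grids:
        counts += np.bincount(grid.labels.ravel().astype(np.int64), minlength=3)[:3]
    return counts / counts.sum()
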