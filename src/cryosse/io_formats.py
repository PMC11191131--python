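"""Density-map and atomic-model I/O.

Grids follow one coordinate convention throughout the package: voxel indices
are 0-based, positions refer to voxel *centers*, and the center of voxel
(i, j, k) sits at ``origin + (i, j, k) * voxel_size`` in the model coordinate
frame (Å).  All distances are Euclidean distances in Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SSClass",
    "DensityMap",
    "Residue",
    "AtomicChain",
    "StrideRecord",
    "StrideAssignment",
    "MapFormatError",
    "ChainLookupError",
    "SizeLimitError",
    "read_density_map",
    "write_density_map",
    "resample_map",
    "read_chain",
    "extract_chain_submap",
    "parse_stride",
]


class SSClass(IntEnum):
    """Three-class secondary-structure encoding used everywhere downstream."""

    BACKGROUND = 0
    HELIX = 1
    SHEET = 2


class MapFormatError(ValueError):
    """Raised for corrupt or truncated MRC/CCP4 files."""


class ChainLookupError(KeyError):
    """Raised when a requested chain id is absent from a model file."""


class SizeLimitError(ValueError):
    """Raised when a chain submap exceeds the allowed number of voxels."""


@dataclass
class DensityMap:
    """A 3D scalar grid with physical metadata.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density values, indexed (i, j, k) along the x, y, z axes.
    voxel_size : ndarray, shape (3,)
        Edge length of a voxel along each axis (Å); strictly positive.
    origin : ndarray, shape (3,)
        Position (Å) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if self.values.ndim != 3:
            raise ValueError(f"density grid must be 3D, got shape {self.values.shape}")
        if np.any(self.voxel_size <= 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std())

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        axes = [
            self.origin[d] + np.arange(self.shape[d]) * self.voxel_size[d]
            for d in range(3)
        ]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return grid

    def index_of(self, position: np.ndarray) -> np.ndarray:
        """Fractional voxel index of a physical position."""
        return (np.asarray(position, dtype=float) - self.origin) / self.voxel_size


@dataclass
class Residue:
    residue_number: int
    amino_acid: str
    ca_position: np.ndarray
    heavy_atom_positions: list[np.ndarray] = field(default_factory=list)
    ss_class: SSClass = SSClass.BACKGROUND

    def __post_init__(self) -> None:
        self.ca_position = np.asarray(self.ca_position, dtype=float).reshape(3)
        self.heavy_atom_positions = [
            np.asarray(p, dtype=float).reshape(3) for p in self.heavy_atom_positions
        ]
        if not self.heavy_atom_positions:
            self.heavy_atom_positions = [self.ca_position]


@dataclass
class AtomicChain:
    chain_id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def ca_positions(self, ss_class: SSClass | None = None) -> np.ndarray:
        """(n, 3) array of Cα positions, optionally restricted to one class."""
        rows = [
            r.ca_position
            for r in self.residues
            if ss_class is None or r.ss_class == ss_class
        ]
        return np.array(rows).reshape(-1, 3)

    def heavy_atom_coords(self) -> np.ndarray:
        rows = [p for r in self.residues for p in r.heavy_atom_positions]
        return np.array(rows).reshape(-1, 3)

    def helix_segments(self, min_length: int = 1) -> list[list[Residue]]:
        """Maximal runs of consecutive helix residues with at least min_length members."""
        runs: list[list[Residue]] = []
        current: list[Residue] = []
        for res in self.residues:
            if res.ss_class == SSClass.HELIX:
                current.append(res)
            else:
                if len(current) >= min_length:
                    runs.append(current)
                current = []
        if len(current) >= min_length:
            runs.append(current)
        return runs


@dataclass
class StrideRecord:
    chain_id: str
    residue_number: int
    stride_code: str


@dataclass
class StrideAssignment:
    records: list[StrideRecord]

    def __len__(self) -> int:
        return len(self.records)

    def code_for(self, chain_id: str, residue_number: int) -> str | None:
        for rec in self.records:
            if rec.chain_id == chain_id and rec.residue_number == residue_number:
                return rec.stride_code
        return None


# ---------------------------------------------------------------------------
# MRC / CCP4 maps
# ---------------------------------------------------------------------------


def read_density_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing any axis permutation to (x, y, z).

    The MAPC/MAPR/MAPS header permutation is resolved on read, so the
    returned grid is always indexed (x, y, z) regardless of storage order.
    """
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot parse {path} as MRC/CCP4: {exc}") from exc
    # nstart along the stored (column, row, section) axes, mapped to x, y, z
    perm = [ccp4.header_i32(17), ccp4.header_i32(18), ccp4.header_i32(19)]
    if sorted(perm) != [1, 2, 3]:
        raise MapFormatError(
            f"invalid MAPC/MAPR/MAPS axis permutation {perm} in {path}"
        )
    nstart_stored = [ccp4.header_i32(5), ccp4.header_i32(6), ccp4.header_i32(7)]
    nstart = np.zeros(3)
    for stored_axis, xyz_axis in enumerate(perm):
        nstart[xyz_axis - 1] = nstart_stored[stored_axis]
    ccp4.setup(float("nan"))
    values = np.array(ccp4.grid, copy=True)
    if np.isnan(values).any():
        raise MapFormatError(f"map {path} does not cover its full grid")
    spacing = np.array(ccp4.grid.spacing, dtype=float)
    if np.any(spacing <= 0):
        raise MapFormatError(f"non-positive voxel spacing {spacing} in {path}")
    origin_words = np.array(
        [ccp4.header_float(50), ccp4.header_float(51), ccp4.header_float(52)],
        dtype=float,
    )
    origin = origin_words + nstart * spacing
    return DensityMap(values=values, voxel_size=spacing, origin=origin)


def write_density_map(density_map: DensityMap, path: str | Path) -> None:
    """Write a map in canonical axis order (mode-2 float MRC/CCP4 2014)."""
    path = Path(path)
    values = np.ascontiguousarray(density_map.values, dtype=np.float32)
    grid = gemmi.FloatGrid(values)
    nx, ny, nz = values.shape
    vx, vy, vz = density_map.voxel_size
    grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), density_map.origin):
        ccp4.set_header_float(word, float(val))
    try:
        ccp4.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map to {path}: {exc}") from exc


def resample_map(density_map: DensityMap, target_voxel: float) -> DensityMap:
    """Resample a map to a new voxel size by trilinear interpolation.

    The output covers the same physical extent (voxel-center span) and keeps
    the origin; a map already at the target spacing is returned value-exact.
    """
    if target_voxel <= 0:
        raise ValueError(f"target voxel size must be positive, got {target_voxel}")
    if np.allclose(density_map.voxel_size, target_voxel):
        return DensityMap(
            values=density_map.values.copy(),
            voxel_size=np.full(3, float(target_voxel)),
            origin=density_map.origin,
        )
    old_shape = np.array(density_map.shape)
    extent = (old_shape - 1) * density_map.voxel_size
    new_shape = np.floor(extent / target_voxel + 1e-9).astype(int) + 1
    scale = target_voxel / density_map.voxel_size
    axes = [np.arange(n) * scale[d] for d, n in enumerate(new_shape)]
    coords = np.meshgrid(*axes, indexing="ij")
    values = map_coordinates(
        density_map.values.astype(np.float64),
        np.stack([c.ravel() for c in coords]),
        order=1,
        mode="nearest",
    ).reshape(tuple(new_shape))
    return DensityMap(
        values=values,
        voxel_size=np.full(3, float(target_voxel)),
        origin=density_map.origin,
    )


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_chain(model_path: str | Path, chain_id: str) -> AtomicChain:
    """Extract one chain (ordered residues, Cα + heavy atoms) from PDB/mmCIF.

    Residues lacking a Cα atom are dropped with a logged warning.
    """
    model_path = Path(model_path)
    structure = gemmi.read_structure(str(model_path))
    structure.remove_hydrogens()
    model = structure[0]
    available = [ch.name for ch in model]
    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        raise ChainLookupError(
            f"chain {chain_id!r} not in {model_path.name}; available: {available}"
        )
    residues: list[Residue] = []
    for res in chain:
        if res.name in _WATER_NAMES:
            continue
        info = gemmi.find_tabulated_residue(res.name)
        one_letter = "X"
        if info is not None and info.is_amino_acid():
            one_letter = info.one_letter_code.upper()
        ca = None
        heavy: list[np.ndarray] = []
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            heavy.append(pos)
            if atom.name == "CA":
                ca = pos
        if ca is None:
            logger.warning(
                "dropping residue %s %d of chain %s: no CA atom",
                res.name,
                res.seqid.num,
                chain_id,
            )
            continue
        residues.append(
            Residue(
                residue_number=res.seqid.num,
                amino_acid=one_letter,
                ca_position=ca,
                heavy_atom_positions=heavy,
            )
        )
    return AtomicChain(chain_id=chain_id, residues=residues)


def extract_chain_submap(
    density_map: DensityMap,
    chain: AtomicChain,
    mask_radius: float = 4.0,
    max_dim: int | None = None,
) -> DensityMap:
    """Crop the bounding box of a chain and mask density not belonging to it.

    The box is the chain's heavy-atom bounding box padded by ``mask_radius``;
    voxels whose centers are farther than ``mask_radius`` from every heavy
    atom are zeroed.  The origin is updated so physical coordinates are
    preserved.  Raises :class:`SizeLimitError` if any output dimension
    exceeds ``max_dim`` voxels.
    """
    if len(chain) == 0:
        raise ValueError("cannot extract a submap for an empty chain")
    if not np.allclose(density_map.voxel_size, 1.0):
        raise ValueError("extract_chain_submap expects a map at 1 Å per voxel")
    atoms = chain.heavy_atom_coords()
    lo_pos = atoms.min(axis=0) - mask_radius
    hi_pos = atoms.max(axis=0) + mask_radius
    lo = np.floor(density_map.index_of(lo_pos)).astype(int)
    hi = np.ceil(density_map.index_of(hi_pos)).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(density_map.shape) - 1)
    dims = hi - lo + 1
    if max_dim is not None:
        for axis, d in enumerate(dims):
            if d > max_dim:
                raise SizeLimitError(
                    f"submap dimension {int(d)} on axis {'xyz'[axis]} exceeds "
                    f"the {max_dim}-voxel limit"
                )
    sub = density_map.values[
        lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1
    ].copy()
    new_origin = density_map.origin + lo * density_map.voxel_size
    submap = DensityMap(values=sub, voxel_size=density_map.voxel_size, origin=new_origin)
    centers = submap.voxel_centers().reshape(-1, 3)
    tree = cKDTree(atoms)
    dist, _ = tree.query(centers, k=1, distance_upper_bound=mask_radius + 1e-9)
    keep = (dist <= mask_radius).reshape(submap.shape)
    submap.values = np.where(keep, submap.values, 0.0).astype(np.float32)
    return submap


# ---------------------------------------------------------------------------
# STRIDE assignments
# ---------------------------------------------------------------------------


def parse_stride(path: str | Path) -> StrideAssignment:
    """Parse the fixed-column ``ASG`` detail lines of a STRIDE output file.

    Non-ASG lines (REM, LOC, ...) are ignored.  One-letter codes are kept
    verbatim, including the lowercase ``b`` bridge code.
    """
    path = Path(path)
    records: list[StrideRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith("ASG"):
                continue
            parts = line.split()
            # ASG <resname> <chain> <pdb-resnum> <ordinal> <code> <full name> ...
            if len(parts) < 6:
                raise ValueError(f"malformed ASG line {lineno} in {path}: {line!r}")
            try:
                resnum = int(parts[3])
            except ValueError as exc:
                raise ValueError(
                    f"malformed ASG line {lineno} in {path}: bad residue number"
                ) from exc
            code = parts[5]
            if len(code) != 1:
                raise ValueError(
                    f"malformed ASG line {lineno} in {path}: bad code {code!r}"
                )
            records.append(StrideRecord(parts[2], resnum, code))
    if not records:
        logger.warning("no ASG lines found in %s: empty assignment", path)
    return StrideAssignment(records=records)


def annotate_chain(
    chain: AtomicChain, assignment: StrideAssignment
) -> AtomicChain:
    """Set each residue's ss_class from a STRIDE assignment (in place)."""
    from .labeling import ss_class_of_code

    lookup = {
        (rec.chain_id, rec.residue_number): rec.stride_code
        for rec in assignment.records
    }
    for res in chain.residues:
        code = lookup.get((chain.chain_id, res.residue_number))
        res.ss_class = ss_class_of_code(code) if code is not None else SSClass.BACKGROUND
    return chain
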