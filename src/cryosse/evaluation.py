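"""Voxel-wise and residue-level evaluation, reports, and threshold sweeps.

Voxel metrics count one-vs-rest true/false positives and negatives per
foreground class.  Residue-level metrics first assign each residue the
majority class of predicted voxels whose centers lie within 3 Å of its Cα
(ties broken helix > sheet > background, mirroring the labeling precedence),
then count one-vs-rest over residues; a class is reported NA for a chain
with zero true residues of that class.  Chain-level F1 values aggregate into
a weighted average using each chain's true-residue (or true-voxel) counts as
weights.

The threshold sweep evaluates a detector at 20 equally spaced density
thresholds from the map mean to five standard deviations above it and
summarizes per-class residue F1 as: the best value, the best-neighborhood
value (mean over three consecutive all-nonzero thresholds around the best),
and the values at fixed 3.25 SD and 2.5 SD thresholds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import AtomicChain, DensityMap, SSClass
from .labeling import VoxelLabelGrid

__all__ = [
    "ChainEvaluation",
    "EvaluationReport",
    "SweepResult",
    "prf_from_counts",
    "voxel_metrics",
    "residue_votes",
    "residue_metrics",
    "weighted_average",
    "evaluate_chain",
    "threshold_sweep",
]

N_SWEEP_THRESHOLDS = 20
SWEEP_SD_SPAN = 5.0
FIXED_SD_LEVELS = (3.25, 2.5)


def prf_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 from counts; zero denominators yield zero."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def voxel_metrics(
    pred: VoxelLabelGrid, truth: VoxelLabelGrid
) -> dict[SSClass, tuple[float, float, float]]:
    """One-vs-rest (P, R, F1) per foreground class over all voxels."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    out = {}
    for ss_class in (SSClass.HELIX, SSClass.SHEET):
        p = pred.labels == int(ss_class)
        t = truth.labels == int(ss_class)
        tp = int(np.count_nonzero(p & t))
        fp = int(np.count_nonzero(p & ~t))
        fn = int(np.count_nonzero(~p & t))
        out[ss_class] = prf_from_counts(tp, fp, fn)
    return out


def residue_votes(
    pred: VoxelLabelGrid, chain: AtomicChain, radius: float = 3.0
) -> list[SSClass]:
    """Majority-vote predicted class per residue from voxels within 3 Å.

    Ties break by precedence helix > sheet > background.  A Cα with no
    in-grid voxels within the radius is predicted background.
    """
    shape = np.array(pred.shape)
    votes: list[SSClass] = []
    # integer offsets within the closed sphere of the given radius
    r_vox = int(math.floor(radius / pred.voxel_size.min())) + 1
    offs = np.array(
        [
            (i, j, k)
            for i in range(-r_vox, r_vox + 1)
            for j in range(-r_vox, r_vox + 1)
            for k in range(-r_vox, r_vox + 1)
        ]
    )
    for res in chain.residues:
        frac = (res.ca_position - pred.origin) / pred.voxel_size
        base = np.round(frac).astype(int)
        cand = base + offs
        centers = pred.origin + cand * pred.voxel_size
        dist = np.linalg.norm(centers - res.ca_position, axis=1)
        in_sphere = dist <= radius
        in_grid = np.all((cand >= 0) & (cand < shape), axis=1)
        sel = cand[in_sphere & in_grid]
        if len(sel) == 0:
            import logging

            logging.getLogger(__name__).warning(
                "residue %d: no in-grid voxels within %.1f Å; predicting background",
                res.residue_number,
                radius,
            )
            votes.append(SSClass.BACKGROUND)
            continue
        labels = pred.labels[sel[:, 0], sel[:, 1], sel[:, 2]]
        counts = np.bincount(labels.astype(np.int64), minlength=3)
        best = max(counts)
        # precedence helix > sheet > background on ties
        for cls in (SSClass.HELIX, SSClass.SHEET, SSClass.BACKGROUND):
            if counts[int(cls)] == best:
                votes.append(cls)
                break
    return votes


def residue_metrics(
    votes: Sequence[SSClass], chain: AtomicChain
) -> dict[SSClass, tuple[float, float, float] | None]:
    """One-vs-rest residue (P, R, F1); NA (None) when a class has no true residues."""
    if len(votes) != len(chain):
        raise ValueError("votes must cover every residue of the chain")
    truth = [res.ss_class for res in chain.residues]
    out: dict[SSClass, tuple[float, float, float] | None] = {}
    for ss_class in (SSClass.HELIX, SSClass.SHEET):
        true_count = sum(1 for t in truth if t == ss_class)
        if true_count == 0:
            out[ss_class] = None
            continue
        tp = sum(1 for v, t in zip(votes, truth) if v == ss_class and t == ss_class)
        fp = sum(1 for v, t in zip(votes, truth) if v == ss_class and t != ss_class)
        fn = sum(1 for v, t in zip(votes, truth) if v != ss_class and t == ss_class)
        out[ss_class] = prf_from_counts(tp, fp, fn)
    return out


@dataclass
class ChainEvaluation:
    """Per-chain metric bundle mirroring one row of the test-set report."""

    chain_key: str
    n_helix_residues: int
    n_sheet_residues: int
    n_total_residues: int
    voxel: dict[SSClass, tuple[float, float, float]]
    residue: dict[SSClass, tuple[float, float, float] | None]
    n_helix_voxels: int = 0
    n_sheet_voxels: int = 0

    def voxel_f1(self, ss_class: SSClass) -> float:
        return self.voxel[ss_class][2]

    def residue_f1(self, ss_class: SSClass) -> float | None:
        entry = self.residue[ss_class]
        return None if entry is None else entry[2]


@dataclass
class EvaluationReport:
    chains: list[ChainEvaluation]

    def weighted_f1(self, ss_class: SSClass, level: str = "residue") -> float | None:
        return weighted_average(self.chains, ss_class, level)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ch in self.chains:
            rows.append(
                {
                    "chain_key": ch.chain_key,
                    "ca_helix": ch.n_helix_residues,
                    "ca_sheet": ch.n_sheet_residues,
                    "ca_total": ch.n_total_residues,
                    "voxel_f1_helix": ch.voxel_f1(SSClass.HELIX),
                    "voxel_f1_sheet": (
                        ch.voxel_f1(SSClass.SHEET)
                        if ch.n_sheet_residues > 0
                        else np.nan
                    ),
                    "residue_f1_helix": (
                        np.nan
                        if ch.residue_f1(SSClass.HELIX) is None
                        else ch.residue_f1(SSClass.HELIX)
                    ),
                    "residue_f1_sheet": (
                        np.nan
                        if ch.residue_f1(SSClass.SHEET) is None
                        else ch.residue_f1(SSClass.SHEET)
                    ),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        agg = {
            "chain_key": "weighted average",
            "ca_helix": sum(c.n_helix_residues for c in self.chains),
            "ca_sheet": sum(c.n_sheet_residues for c in self.chains),
            "ca_total": sum(c.n_total_residues for c in self.chains),
            "residue_f1_helix": self.weighted_f1(SSClass.HELIX, "residue"),
            "residue_f1_sheet": self.weighted_f1(SSClass.SHEET, "residue"),
            "voxel_f1_helix": self.weighted_f1(SSClass.HELIX, "voxel"),
            "voxel_f1_sheet": self.weighted_f1(SSClass.SHEET, "voxel"),
        }
        df = pd.concat([df, pd.DataFrame([agg])], ignore_index=True)
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")

    def write_json(self, path: str | Path) -> None:
        payload = []
        for ch in self.chains:
            payload.append(
                {
                    "chain_key": ch.chain_key,
                    "counts": {
                        "helix": ch.n_helix_residues,
                        "sheet": ch.n_sheet_residues,
                        "total": ch.n_total_residues,
                    },
                    "voxel": {
                        cls.name.lower(): list(ch.voxel[cls])
                        for cls in (SSClass.HELIX, SSClass.SHEET)
                    },
                    "residue": {
                        cls.name.lower(): (
                            None if ch.residue[cls] is None else list(ch.residue[cls])
                        )
                        for cls in (SSClass.HELIX, SSClass.SHEET)
                    },
                }
            )
        Path(path).write_text(json.dumps(payload, indent=2))


def weighted_average(
    chains: Sequence[ChainEvaluation],
    ss_class: SSClass,
    level: str = "residue",
) -> float | None:
    """Aggregate F1 weighted by each chain's true-class residue count.

    Chains with zero true residues of the class (NA) are excluded; returns
    None when every chain is NA for the class.
    """
    if not chains:
        raise ValueError("weighted_average requires at least one chain report")
    total_weight = 0
    acc = 0.0
    for ch in chains:
        weight = (
            ch.n_helix_residues if ss_class == SSClass.HELIX else ch.n_sheet_residues
        )
        if weight == 0:
            continue
        f1 = ch.voxel_f1(ss_class) if level == "voxel" else ch.residue_f1(ss_class)
        if f1 is None:
            continue
        acc += weight * f1
        total_weight += weight
    if total_weight == 0:
        return None
    return acc / total_weight


def evaluate_chain(
    chain_key: str,
    pred: VoxelLabelGrid,
    truth: VoxelLabelGrid,
    chain: AtomicChain,
    radius: float = 3.0,
) -> ChainEvaluation:
    """Full voxel + residue evaluation of one chain prediction."""
    votes = residue_votes(pred, chain, radius=radius)
    return ChainEvaluation(
        chain_key=chain_key,
        n_helix_residues=sum(
            1 for r in chain.residues if r.ss_class == SSClass.HELIX
        ),
        n_sheet_residues=sum(
            1 for r in chain.residues if r.ss_class == SSClass.SHEET
        ),
        n_total_residues=len(chain),
        voxel=voxel_metrics(pred, truth),
        residue=residue_metrics(votes, chain),
        n_helix_voxels=int(np.count_nonzero(truth.labels == int(SSClass.HELIX))),
        n_sheet_voxels=int(np.count_nonzero(truth.labels == int(SSClass.SHEET))),
    )


@dataclass
class SweepResult:
    """Residue-F1 statistics of a detector across the 20-threshold grid."""

    thresholds: np.ndarray
    f1_per_threshold: dict[SSClass, np.ndarray]
    best_f1: dict[SSClass, float]
    best_nbr_f1: dict[SSClass, float]
    fixed_sd_f1: dict[float, dict[SSClass, float]]


def _best_neighborhood(f1: np.ndarray, best_idx: int) -> float:
    """Mean of three consecutive all-nonzero F1 values around the best index.

    Preference order: the centered triple, then the left- and right-shifted
    triples; if no triple qualifies, the mean of the nonzero values among
    the centered triple (clipped to the grid); zero if none are nonzero.
    """
    n = len(f1)
    candidates = [
        (best_idx - 1, best_idx, best_idx + 1),
        (best_idx - 2, best_idx - 1, best_idx),
        (best_idx, best_idx + 1, best_idx + 2),
    ]
    for triple in candidates:
        if min(triple) < 0 or max(triple) >= n:
            continue
        vals = f1[list(triple)]
        if np.all(vals > 0):
            return float(vals.mean())
    centered = [i for i in candidates[0] if 0 <= i < n]
    vals = [f1[i] for i in centered if f1[i] > 0]
    return float(np.mean(vals)) if vals else 0.0


def threshold_sweep(
    density_map: DensityMap,
    detector: Callable[[DensityMap, float], VoxelLabelGrid],
    chain: AtomicChain,
    radius: float = 3.0,
) -> SweepResult:
    """Residue-level F1 of a threshold-parametrized detector over the grid
    t_i = μ + i·5σ/19, i = 0..19."""
    mu, sd = density_map.mean, density_map.sd
    if sd == 0:
        raise ValueError("degenerate map: zero standard deviation")
    thresholds = mu + np.arange(N_SWEEP_THRESHOLDS) * (
        SWEEP_SD_SPAN * sd / (N_SWEEP_THRESHOLDS - 1)
    )
    f1s: dict[SSClass, list[float]] = {SSClass.HELIX: [], SSClass.SHEET: []}
    for threshold in thresholds:
        pred = detector(density_map, float(threshold))
        votes = residue_votes(pred, chain, radius=radius)
        metrics = residue_metrics(votes, chain)
        for ss_class in (SSClass.HELIX, SSClass.SHEET):
            entry = metrics[ss_class]
            f1s[ss_class].append(0.0 if entry is None else entry[2])
    f1_arrays = {cls: np.array(vals) for cls, vals in f1s.items()}
    best = {cls: float(arr.max()) for cls, arr in f1_arrays.items()}
    best_nbr = {
        cls: _best_neighborhood(arr, int(arr.argmax()))
        for cls, arr in f1_arrays.items()
    }
    fixed = {}
    for level in FIXED_SD_LEVELS:
        target = mu + level * sd
        idx = int(np.abs(thresholds - target).argmin())
        fixed[level] = {cls: float(arr[idx]) for cls, arr in f1_arrays.items()}
    return SweepResult(
        thresholds=thresholds,
        f1_per_threshold=f1_arrays,
        best_f1=best,
        best_nbr_f1=best_nbr,
        fixed_sd_f1=fixed,
    )
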