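"""Data curation: dedup by sequence identity, quality scoring, bins, splits.

Chains are deduplicated with Needleman-Wunsch global alignments (match +1,
mismatch -1, gap -2; identity = identical aligned positions / alignment
length).  Map-model agreement is scored by a simplified cylindrical helix
fit: each helix of at least four residues gets a least-squares axis and a
2.5 Å cylinder over its axial extent, and the F1 of above-threshold voxels
against that cylinder summarizes how helix-like the density is.  The chain
score (mean F1 over helices) and the precision-recall difference place each
chain in one of four quality bins; bin 4 (worst) is excluded from modelling
upstream of the split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .io_formats import AtomicChain, DensityMap, SSClass

logger = logging.getLogger(__name__)

__all__ = [
    "QualityRecord",
    "SplitAssignment",
    "nw_identity",
    "deduplicate",
    "check_split_identity",
    "helix_cylinder_fit",
    "assign_bin",
    "size_filter",
    "stratified_split",
]

NW_MATCH = 1.0
NW_MISMATCH = -1.0
NW_GAP = -2.0
DEDUP_IDENTITY_THRESHOLD = 0.70
SPLIT_MAX_IDENTITY = 0.35
CYLINDER_RADIUS = 2.5          # Å, stand-in constant of the helix fit
CYLINDER_NEIGHBORHOOD = 5.0    # Å, precision counts voxels this close to the cylinder
MIN_HELIX_RESIDUES = 4
SIZE_LIMIT_VOXELS = 100


@dataclass
class QualityRecord:
    chain_key: str
    helix_fit_precision: float
    helix_fit_recall: float
    helix_fit_f1: float
    pr_difference: float
    bin: int

    @classmethod
    def from_fit(
        cls, chain_key: str, precision: float, recall: float, f1: float
    ) -> "QualityRecord":
        pr_diff = abs(precision - recall)
        return cls(
            chain_key=chain_key,
            helix_fit_precision=precision,
            helix_fit_recall=recall,
            helix_fit_f1=f1,
            pr_difference=pr_diff,
            bin=assign_bin(f1, pr_diff),
        )


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # chain_key -> "train" | "validation" | "test"

    def keys_for(self, subset: str) -> list[str]:
        return [k for k, v in self.assignment.items() if v == subset]


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------


def nw_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity between two amino-acid sequences.

    Needleman-Wunsch with match +1, mismatch -1, gap -2.  Identity is the
    number of identical aligned positions divided by the alignment length
    (gap columns included).  Among score-optimal alignments the one with the
    most identical positions (then the shortest) defines the identity, which
    makes the value deterministic.  ``X`` is tolerated but never counts as a
    match, even against another ``X``.
    """
    if not seq_a or not seq_b:
        raise ValueError("nw_identity requires two nonempty sequences")
    n, m = len(seq_a), len(seq_b)
    # DP over (score, matches, -length), maximized lexicographically; all
    # three components are additive along an alignment, so the Bellman
    # recursion applies to the tuple as a whole.
    neg_inf = (-np.inf, 0, 0)
    prev = [(NW_GAP * j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [neg_inf] * (m + 1)
        cur[0] = (NW_GAP * i, 0, -i)
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            bj = seq_b[j - 1]
            is_match = ai == bj and ai != "X"
            sub = NW_MATCH if is_match else NW_MISMATCH
            ps, pm, pl = prev[j - 1]
            diag = (ps + sub, pm + (1 if is_match else 0), pl - 1)
            us, um, ul = prev[j]
            up = (us + NW_GAP, um, ul - 1)
            ls, lm, ll = cur[j - 1]
            left = (ls + NW_GAP, lm, ll - 1)
            cur[j] = max(diag, up, left)
        prev = cur
    _, matches, neg_length = prev[m]
    return matches / (-neg_length)


def deduplicate(
    chains: Sequence[AtomicChain],
    threshold: float = DEDUP_IDENTITY_THRESHOLD,
) -> list[AtomicChain]:
    """Greedy in-order dedup: drop a chain whose identity with any retained
    chain strictly exceeds ``threshold``."""
    if not chains:
        raise ValueError("deduplicate requires at least one chain")
    retained: list[AtomicChain] = []
    for chain in chains:
        duplicate_of = None
        for kept in retained:
            if nw_identity(chain.sequence, kept.sequence) > threshold:
                duplicate_of = kept
                break
        if duplicate_of is None:
            retained.append(chain)
        else:
            logger.info(
                "dropping chain %s: > %.0f%% identity with retained chain %s",
                chain.chain_id,
                100 * threshold,
                duplicate_of.chain_id,
            )
    return retained


@dataclass
class SplitIdentityReport:
    violations: list[tuple[int, int, float]]  # (train index, test index, identity)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.passed:
            return "pass: no train/test pair exceeds the identity ceiling"
        lines = [
            f"fail: {len(self.violations)} train/test pair(s) exceed the ceiling"
        ]
        for ti, si, ident in self.violations:
            lines.append(f"  train[{ti}] vs test[{si}]: identity {ident:.3f}")
        return "\n".join(lines)


def check_split_identity(
    train_seqs: Sequence[str],
    test_seqs: Sequence[str],
    max_identity: float = SPLIT_MAX_IDENTITY,
) -> SplitIdentityReport:
    """Report every (train, test) sequence pair above ``max_identity``."""
    if not train_seqs or not test_seqs:
        raise ValueError("both sequence sets must be nonempty")
    violations = []
    for ti, train_seq in enumerate(train_seqs):
        for si, test_seq in enumerate(test_seqs):
            ident = nw_identity(train_seq, test_seq)
            if ident > max_identity:
                violations.append((ti, si, ident))
    return SplitIdentityReport(violations=violations)


# ---------------------------------------------------------------------------
# Cylindrical helix fit (simplified map-model agreement score)
# ---------------------------------------------------------------------------


def _cylinder_distances(
    points: np.ndarray, centroid: np.ndarray, axis: np.ndarray, t_min: float, t_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Radial distance to the axis and axial overshoot beyond the extent."""
    rel = points - centroid
    t = rel @ axis
    radial = np.linalg.norm(rel - np.outer(t, axis), axis=1)
    axial_over = np.maximum(np.maximum(t_min - t, t - t_max), 0.0)
    return radial, axial_over


def helix_cylinder_fit(
    density_map: DensityMap,
    chain: AtomicChain,
    threshold: float,
) -> tuple[list[tuple[float, float, float]], QualityRecord]:
    """Score map-model helix agreement with a cylinder fit.

    Per helix (>= 4 residues): the axis is the least-squares line through the
    helix Cα atoms, the cylinder has radius 2.5 Å and spans the axial extent
    of the helix.  Precision is the fraction of above-threshold voxels inside
    the cylinder among above-threshold voxels within 5 Å of it; recall is the
    fraction of cylinder voxels above threshold.  The chain score is the mean
    F1 over helices.
    """
    helices = chain.helix_segments(min_length=MIN_HELIX_RESIDUES)
    if not helices:
        raise ValueError(
            f"chain {chain.chain_id} has no helix of >= {MIN_HELIX_RESIDUES} residues; "
            "quality is undefined"
        )
    centers = density_map.voxel_centers().reshape(-1, 3)
    above = density_map.values.ravel() > threshold
    per_helix: list[tuple[float, float, float]] = []
    for helix in helices:
        cas = np.array([r.ca_position for r in helix])
        centroid = cas.mean(axis=0)
        _, _, vt = np.linalg.svd(cas - centroid, full_matrices=False)
        axis = vt[0] / np.linalg.norm(vt[0])
        t_ca = (cas - centroid) @ axis
        radial, axial_over = _cylinder_distances(
            centers, centroid, axis, t_ca.min(), t_ca.max()
        )
        inside = (radial <= CYLINDER_RADIUS) & (axial_over == 0.0)
        near = (
            np.sqrt(np.maximum(radial - CYLINDER_RADIUS, 0.0) ** 2 + axial_over**2)
            <= CYLINDER_NEIGHBORHOOD
        )
        pred_near = above & near
        precision = (
            float((above & inside).sum()) / pred_near.sum() if pred_near.any() else 0.0
        )
        recall = float((above & inside).sum()) / inside.sum() if inside.any() else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_helix.append((precision, recall, f1))
    mean_p = float(np.mean([p for p, _, _ in per_helix]))
    mean_r = float(np.mean([r for _, r, _ in per_helix]))
    mean_f1 = float(np.mean([f for _, _, f in per_helix]))
    record = QualityRecord.from_fit(chain.chain_id, mean_p, mean_r, mean_f1)
    return per_helix, record


def assign_bin(score: float, pr_diff: float) -> int:
    """Quality bin from the chain score (mean helix-fit F1) and |P - R|.

    Bin 1: score >= 0.7.  Bin 2: score in [0.6, 0.7) with pr_diff < 0.15.
    Bin 3: score in [0.6, 0.7) with pr_diff >= 0.15, or score in [0.55, 0.6)
    with pr_diff < 0.15.  Bin 4: everything else.
    """
    if not (0.0 <= score <= 1.0) or not (0.0 <= pr_diff <= 1.0):
        raise ValueError(
            f"score and pr_diff must lie in [0, 1], got {score}, {pr_diff}"
        )
    if score >= 0.7:
        return 1
    if 0.6 <= score < 0.7:
        return 2 if pr_diff < 0.15 else 3
    if 0.55 <= score < 0.6 and pr_diff < 0.15:
        return 3
    return 4


def size_filter(
    items: Sequence[tuple[object, tuple[int, int, int]]],
    max_dim: int = SIZE_LIMIT_VOXELS,
) -> list[object]:
    """Keep items whose submap dims are all <= ``max_dim`` (inclusive limit).

    ``items`` are (payload, dims) pairs; drops are logged.
    """
    kept = []
    for payload, dims in items:
        if max(dims) > max_dim:
            logger.info("size filter: dropping %r with dims %s", payload, dims)
        else:
            kept.append(payload)
    return kept


def stratified_split(
    records: Sequence[QualityRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Bin-stratified train/validation/test partition.

    Within each bin, chains are shuffled with ``seed`` and allocated
    proportionally; the rounding remainder goes to train.  Records must all
    be in bins 1-3 (bin 4 is excluded upstream).
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    for rec in records:
        if rec.bin not in (1, 2, 3):
            raise ValueError(
                f"chain {rec.chain_key} is in bin {rec.bin}; only bins 1-3 are split"
            )
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for bin_id in (1, 2, 3):
        keys = [r.chain_key for r in records if r.bin == bin_id]
        if not keys:
            continue
        order = rng.permutation(len(keys))
        keys = [keys[i] for i in order]
        n = len(keys)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        if n < 3 and (fractions[1] > 0 or fractions[2] > 0):
            logger.warning(
                "bin %d has only %d chain(s); assigning all of them to train",
                bin_id,
                n,
            )
            n_train, n_val, n_test = n, 0, 0
        for idx, key in enumerate(keys):
            if idx < n_train:
                assignment[key] = "train"
            elif idx < n_train + n_val:
                assignment[key] = "validation"
            else:
                assignment[key] = "test"
    return SplitAssignment(assignment=assignment)
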