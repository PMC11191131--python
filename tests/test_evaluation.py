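import numpy as np
import pytest

from cryosse.evaluation import (
    ChainEvaluation,
    EvaluationReport,
    _best_neighborhood,
    evaluate_chain,
    prf_from_counts,
    residue_metrics,
    residue_votes,
    threshold_sweep,
    voxel_metrics,
    weighted_average,
)
from cryosse.io_formats import AtomicChain, DensityMap, Residue, SSClass
from cryosse.labeling import VoxelLabelGrid, label_voxels


class TestPrfFromCounts:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected",
        [
            (10, 0, 0, (1.0, 1.0, 1.0)),
            (8, 2, 4, (0.8, 8 / 12, 0.7273)),
            (0, 0, 0, (0.0, 0.0, 0.0)),
            (0, 5, 5, (0.0, 0.0, 0.0)),
        ],
    )
    def test_examples(self, tp, fp, fn, expected):
        p, r, f1 = prf_from_counts(tp, fp, fn)
        assert p == pytest.approx(expected[0], abs=1e-4)
        assert r == pytest.approx(expected[1], abs=1e-4)
        assert f1 == pytest.approx(expected[2], abs=1e-4)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf_from_counts(-1, 0, 0)


def _grid_from(labels):
    return VoxelLabelGrid(labels=np.asarray(labels, dtype=np.int8))


class TestVoxelMetrics:
    def test_perfect_prediction(self):
        labels = np.random.default_rng(0).integers(0, 3, size=(8, 8, 8))
        metrics = voxel_metrics(_grid_from(labels), _grid_from(labels))
        assert metrics[SSClass.HELIX][2] == 1.0
        assert metrics[SSClass.SHEET][2] == 1.0

    def test_all_background_prediction_has_zero_recall(self):
        truth = np.zeros((6, 6, 6), dtype=int)
        truth[2:4, 2:4, 2:4] = 1
        metrics = voxel_metrics(
            _grid_from(np.zeros((6, 6, 6))), _grid_from(truth)
        )
        assert metrics[SSClass.HELIX][1] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            voxel_metrics(
                _grid_from(np.zeros((4, 4, 4))), _grid_from(np.zeros((5, 5, 5)))
            )

    def test_matches_brute_force_counting_on_random_grids(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            pred = rng.integers(0, 3, size=(10, 10, 10))
            truth = rng.integers(0, 3, size=(10, 10, 10))
            metrics = voxel_metrics(_grid_from(pred), _grid_from(truth))
            for cls in (1, 2):
                tp = fp = fn = 0
                for idx in np.ndindex(pred.shape):
                    p, t = pred[idx] == cls, truth[idx] == cls
                    tp += p and t
                    fp += p and not t
                    fn += t and not p
                expected = prf_from_counts(tp, fp, fn)
                assert metrics[SSClass(cls)] == pytest.approx(expected)

    def test_swapping_classes_swaps_metrics(self):
        rng = np.random.default_rng(2)
        pred = rng.integers(0, 3, size=(8, 8, 8))
        truth = rng.integers(0, 3, size=(8, 8, 8))
        swap = {0: 0, 1: 2, 2: 1}
        pred_s = np.vectorize(swap.get)(pred)
        truth_s = np.vectorize(swap.get)(truth)
        m = voxel_metrics(_grid_from(pred), _grid_from(truth))
        ms = voxel_metrics(_grid_from(pred_s), _grid_from(truth_s))
        assert m[SSClass.HELIX] == pytest.approx(ms[SSClass.SHEET])
        assert m[SSClass.SHEET] == pytest.approx(ms[SSClass.HELIX])


def _single_residue_chain(position, ss_class=SSClass.HELIX):
    return AtomicChain("A", [Residue(1, "A", position, ss_class=ss_class)])


class TestResidueVotes:
    def test_unanimous_helix_sphere(self):
        labels = np.ones((20, 20, 20), dtype=np.int8)
        grid = VoxelLabelGrid(labels=labels)
        votes = residue_votes(grid, _single_residue_chain([10.0, 10.0, 10.0]))
        assert votes == [SSClass.HELIX]

    def test_strict_majority_background_wins(self):
        # 61 helix vs 62 background among the 123 in-sphere voxels
        labels = np.zeros((20, 20, 20), dtype=np.int8)
        grid0 = VoxelLabelGrid(labels=labels.copy())
        chain = _single_residue_chain([10.0, 10.0, 10.0])
        # collect the in-sphere voxels and set exactly 61 of them to helix
        coords = [
            (x, y, z)
            for x in range(20)
            for y in range(20)
            for z in range(20)
            if (x - 10) ** 2 + (y - 10) ** 2 + (z - 10) ** 2 <= 9
        ]
        assert len(coords) == 123
        for x, y, z in coords[:61]:
            labels[x, y, z] = 1
        votes = residue_votes(VoxelLabelGrid(labels=labels), chain)
        assert votes == [SSClass.BACKGROUND]
        for x, y, z in coords[61:62]:
            labels[x, y, z] = 1
        votes = residue_votes(VoxelLabelGrid(labels=labels), chain)
        assert votes == [SSClass.HELIX]

    def test_tie_breaks_by_helix_precedence(self):
        labels = np.zeros((20, 20, 20), dtype=np.int8)
        coords = [
            (x, y, z)
            for x in range(20)
            for y in range(20)
            for z in range(20)
            if (x - 10) ** 2 + (y - 10) ** 2 + (z - 10) ** 2 <= 9
        ]
        for x, y, z in coords[:50]:
            labels[x, y, z] = 1
        for x, y, z in coords[50:100]:
            labels[x, y, z] = 2
        votes = residue_votes(
            VoxelLabelGrid(labels=labels), _single_residue_chain([10.0, 10.0, 10.0])
        )
        assert votes == [SSClass.HELIX]

    def test_ca_outside_grid_predicts_background_with_warning(self, caplog):
        grid = VoxelLabelGrid(labels=np.ones((5, 5, 5), dtype=np.int8))
        chain = _single_residue_chain([50.0, 50.0, 50.0])
        with caplog.at_level("WARNING"):
            votes = residue_votes(grid, chain)
        assert votes == [SSClass.BACKGROUND]

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            shape = (12, 12, 12)
            labels = rng.integers(0, 3, size=shape).astype(np.int8)
            grid = VoxelLabelGrid(labels=labels)
            chain = AtomicChain(
                "A",
                [
                    Residue(
                        i + 1,
                        "A",
                        rng.uniform(0, 11, size=3),
                        ss_class=SSClass(rng.integers(0, 3)),
                    )
                    for i in range(4)
                ],
            )
            votes = residue_votes(grid, chain)
            for res, vote in zip(chain.residues, votes):
                counts = [0, 0, 0]
                for idx in np.ndindex(shape):
                    if np.linalg.norm(np.array(idx) - res.ca_position) <= 3.0:
                        counts[labels[idx]] += 1
                best = max(counts)
                expected = next(
                    cls
                    for cls in (SSClass.HELIX, SSClass.SHEET, SSClass.BACKGROUND)
                    if counts[int(cls)] == best
                )
                assert vote == expected


class TestResidueMetrics:
    def _chain(self, classes):
        return AtomicChain(
            "A",
            [
                Residue(i + 1, "A", [float(i), 0, 0], ss_class=c)
                for i, c in enumerate(classes)
            ],
        )

    def test_perfect_votes(self):
        chain = self._chain([SSClass.HELIX, SSClass.SHEET, SSClass.BACKGROUND])
        votes = [r.ss_class for r in chain.residues]
        metrics = residue_metrics(votes, chain)
        assert metrics[SSClass.HELIX][2] == 1.0
        assert metrics[SSClass.SHEET][2] == 1.0

    def test_class_without_true_residues_is_na(self):
        chain = self._chain([SSClass.HELIX, SSClass.HELIX, SSClass.BACKGROUND])
        votes = [SSClass.HELIX, SSClass.HELIX, SSClass.SHEET]
        metrics = residue_metrics(votes, chain)
        assert metrics[SSClass.SHEET] is None  # NA despite a false positive

    def test_hand_built_example_matches_brute_force(self):
        chain = self._chain(
            [
                SSClass.HELIX,
                SSClass.HELIX,
                SSClass.SHEET,
                SSClass.SHEET,
                SSClass.BACKGROUND,
                SSClass.BACKGROUND,
            ]
        )
        votes = [
            SSClass.HELIX,
            SSClass.SHEET,
            SSClass.SHEET,
            SSClass.BACKGROUND,
            SSClass.BACKGROUND,
            SSClass.HELIX,
        ]
        metrics = residue_metrics(votes, chain)
        # helix: tp=1, fp=1, fn=1 -> P=R=F1=0.5
        assert metrics[SSClass.HELIX] == pytest.approx((0.5, 0.5, 0.5))
        # sheet: tp=1, fp=1, fn=1 -> 0.5 across the board
        assert metrics[SSClass.SHEET] == pytest.approx((0.5, 0.5, 0.5))

    def test_vote_count_mismatch_rejected(self):
        chain = self._chain([SSClass.HELIX])
        with pytest.raises(ValueError):
            residue_metrics([], chain)


def _evaluation(chain_key, helix_count, sheet_count, helix_f1, sheet_f1):
    return ChainEvaluation(
        chain_key=chain_key,
        n_helix_residues=helix_count,
        n_sheet_residues=sheet_count,
        n_total_residues=helix_count + sheet_count,
        voxel={
            SSClass.HELIX: (helix_f1, helix_f1, helix_f1),
            SSClass.SHEET: (sheet_f1 or 0, sheet_f1 or 0, sheet_f1 or 0),
        },
        residue={
            SSClass.HELIX: (helix_f1, helix_f1, helix_f1),
            SSClass.SHEET: None if sheet_f1 is None else (sheet_f1,) * 3,
        },
    )


class TestWeightedAverage:
    def test_identical_chains_average_to_common_value(self):
        chains = [_evaluation(f"c{i}", 10, 5, 0.7, 0.4) for i in range(3)]
        assert weighted_average(chains, SSClass.HELIX) == pytest.approx(0.7)

    def test_count_weighted_combination(self):
        chains = [
            _evaluation("a", 10, 0, 0.5, None),
            _evaluation("b", 30, 0, 0.9, None),
        ]
        assert weighted_average(chains, SSClass.HELIX) == pytest.approx(0.8)

    def test_all_na_gives_none(self):
        chains = [_evaluation("a", 10, 0, 0.5, None)]
        assert weighted_average(chains, SSClass.SHEET) is None

    def test_invariant_to_chain_ordering_and_splitting(self):
        chains = [
            _evaluation("a", 10, 4, 0.5, 0.3),
            _evaluation("b", 30, 6, 0.9, 0.7),
        ]
        rev = weighted_average(list(reversed(chains)), SSClass.HELIX)
        assert weighted_average(chains, SSClass.HELIX) == pytest.approx(rev)
        # splitting chain b into two chains with identical per-class F1
        split = [
            chains[0],
            _evaluation("b1", 15, 3, 0.9, 0.7),
            _evaluation("b2", 15, 3, 0.9, 0.7),
        ]
        assert weighted_average(chains, SSClass.HELIX) == pytest.approx(
            weighted_average(split, SSClass.HELIX)
        )


class TestThresholdSweep:
    def _fixture(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(16, 16, 16)).astype(np.float32)
        density = DensityMap(values=values)
        chain = AtomicChain(
            "A",
            [
                Residue(1, "A", [4.0, 8.0, 8.0], ss_class=SSClass.HELIX),
                Residue(2, "A", [11.0, 8.0, 8.0], ss_class=SSClass.SHEET),
            ],
        )
        truth = label_voxels(chain, density)
        return density, chain, truth

    def test_threshold_grid_is_exact(self):
        density, chain, truth = self._fixture()
        result = threshold_sweep(
            density, lambda m, t: truth, chain
        )
        mu, sd = density.mean, density.sd
        expected = mu + np.arange(20) * 5.0 * sd / 19.0
        np.testing.assert_allclose(result.thresholds, expected, rtol=1e-9)

    def test_truth_detector_scores_one_everywhere(self):
        density, chain, truth = self._fixture()
        result = threshold_sweep(density, lambda m, t: truth, chain)
        for cls in (SSClass.HELIX, SSClass.SHEET):
            assert result.best_f1[cls] == 1.0
            assert result.best_nbr_f1[cls] == 1.0
            for level in (3.25, 2.5):
                assert result.fixed_sd_f1[level][cls] == 1.0

    def test_best_dominates_best_neighborhood_for_arbitrary_detectors(self):
        density, chain, truth = self._fixture()
        rng = np.random.default_rng(1)

        def noisy_detector(m, t):
            labels = truth.labels.copy()
            flip = rng.random(labels.shape) < min(abs(t), 0.9)
            labels[flip] = 0
            return VoxelLabelGrid(labels=labels)

        result = threshold_sweep(density, noisy_detector, chain)
        for cls in (SSClass.HELIX, SSClass.SHEET):
            assert result.best_f1[cls] >= result.best_nbr_f1[cls] >= 0.0

    def test_degenerate_map_rejected(self):
        density = DensityMap(values=np.zeros((8, 8, 8), dtype=np.float32))
        chain = AtomicChain(
            "A", [Residue(1, "A", [4.0, 4.0, 4.0], ss_class=SSClass.HELIX)]
        )
        with pytest.raises(ValueError, match="degenerate"):
            threshold_sweep(density, lambda m, t: None, chain)


class TestBestNeighborhood:
    def test_centered_triple_preferred(self):
        f1 = np.array([0.1, 0.5, 0.9, 0.6, 0.2])
        assert _best_neighborhood(f1, 2) == pytest.approx(np.mean([0.5, 0.9, 0.6]))

    def test_shifted_triple_when_neighbor_is_zero(self):
        f1 = np.array([0.2, 0.5, 0.9, 0.0, 0.1])
        assert _best_neighborhood(f1, 2) == pytest.approx(np.mean([0.2, 0.5, 0.9]))

    def test_partial_fallback_when_no_triple_qualifies(self):
        f1 = np.array([0.0, 0.0, 0.9, 0.0, 0.0])
        assert _best_neighborhood(f1, 2) == pytest.approx(0.9)

    def test_best_at_grid_edge(self):
        f1 = np.array([0.9, 0.5, 0.4, 0.0, 0.0])
        assert _best_neighborhood(f1, 0) == pytest.approx(np.mean([0.9, 0.5, 0.4]))


class TestEvaluateChainAndReport:
    def test_report_roundtrip_on_labeled_fixture(self, tmp_path):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 3, size=(10, 10, 10)).astype(np.int8)
        truth = VoxelLabelGrid(labels=labels)
        pred = VoxelLabelGrid(labels=labels.copy())
        chain = AtomicChain(
            "A",
            [
                Residue(1, "A", [3.0, 3.0, 3.0], ss_class=SSClass.HELIX),
                Residue(2, "A", [7.0, 7.0, 7.0], ss_class=SSClass.SHEET),
            ],
        )
        evaluation = evaluate_chain("fixture", pred, truth, chain)
        report = EvaluationReport(chains=[evaluation])
        tsv = tmp_path / "report.tsv"
        report.write_tsv(tsv)
        assert "weighted average" in tsv.read_text()
        js = tmp_path / "report.json"
        report.write_json(js)
        assert "fixture" in js.read_text()
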