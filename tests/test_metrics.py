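import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lesionwise import (
    EvalParams,
    LabelMap,
    cohort_summary,
    dice,
    evaluate_case,
    hd95,
    lesionwise_scores,
    match_lesions,
    running_average_by_volume,
)
from lesionwise.errors import (
    ComparisonError,
    DegenerateCohortError,
    UndefinedDistanceError,
)
from lesionwise.label_io import REGIONS, RegionMask
from lesionwise.metrics import LesionRecord

from oracles import brute_hd95

ET = REGIONS["ET"]


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return RegionMask(np.asarray(arr, bool), ET, spacing)


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        m = rng.random((8, 8, 8)) < 0.3
        assert dice(_mask(m), _mask(m)) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[1, 1, 1] = b[4, 4, 4] = True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_both_empty_is_one_by_convention(self):
        z = np.zeros((4, 4, 4), bool)
        assert dice(_mask(z), _mask(z)) == 1.0

    def test_matches_voxel_count_oracle(self, rng):
        for _ in range(50):
            a = rng.random((8, 8, 8)) < 0.3
            b = rng.random((8, 8, 8)) < 0.3
            inter = int((a & b).sum())
            expected = 1.0 if a.sum() + b.sum() == 0 else 2 * inter / (a.sum() + b.sum())
            assert dice(_mask(a), _mask(b)) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
    def test_symmetry(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(12)], bool).reshape(3, 2, 2)
        b = np.array([(bits_b >> i) & 1 for i in range(12)], bool).reshape(3, 2, 2)
        assert dice(_mask(a), _mask(b)) == dice(_mask(b), _mask(a))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ComparisonError):
            dice(_mask(np.zeros((4, 4, 4))), _mask(np.zeros((4, 4, 5))))


class TestHd95:
    def test_identical_masks_zero(self, rng):
        m = rng.random((8, 8, 8)) < 0.3
        m[3, 3, 3] = True
        assert hd95(_mask(m), _mask(m)) == 0.0

    def test_two_voxels_five_mm_apart(self):
        a = np.zeros((12, 12, 12), bool)
        b = np.zeros((12, 12, 12), bool)
        a[2, 2, 2] = True
        b[7, 2, 2] = True
        assert hd95(_mask(a), _mask(b)) == pytest.approx(5.0)

    def test_empty_mask_raises(self):
        m = np.zeros((4, 4, 4), bool)
        full = m.copy()
        full[1, 1, 1] = True
        with pytest.raises(UndefinedDistanceError):
            hd95(_mask(m), _mask(full))

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(60):
            shape = tuple(rng.integers(5, 13, 3))
            a = rng.random(shape) < 0.25
            b = rng.random(shape) < 0.25
            if not a.any() or not b.any():
                continue
            assert hd95(_mask(a), _mask(b)) == pytest.approx(
                brute_hd95(a, b), abs=1e-9
            )

    def test_anisotropic_spacing_respected(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 2] = True
        b[2, 2, 4] = True  # 2 voxels along z at 3 mm spacing
        assert hd95(_mask(a, (1, 1, 3)), _mask(b, (1, 1, 3)), (1, 1, 3)) == pytest.approx(6.0)

    def test_symmetry(self, rng):
        a = rng.random((8, 8, 8)) < 0.3
        b = rng.random((8, 8, 8)) < 0.3
        a[2, 2, 2] = b[5, 5, 5] = True
        assert hd95(_mask(a), _mask(b)) == hd95(_mask(b), _mask(a))


class TestLesionwiseScores:
    def test_single_missed_lesion_gets_full_penalties(self, single_lesion_case):
        gt, pred = single_lesion_case
        scores = evaluate_case(gt, pred).regions["ET"]
        assert scores.lesionwise_dice == 0.0
        assert scores.lesionwise_hd95 == 374.0

    def test_exact_prediction_is_perfect(self, single_lesion_case):
        gt, _ = single_lesion_case
        scores = evaluate_case(gt, gt).regions["ET"]
        assert scores.lesionwise_dice == 1.0
        assert scores.lesionwise_hd95 == 0.0

    def test_one_tp_plus_one_fp_halves_dice(self):
        # TP lesion with partial overlap dice d, plus one disjoint FP:
        # numerator d, denominator TP+FN+FP = 2
        gt = np.zeros((32, 32, 32), bool)
        gt[4:8, 4:8, 4:8] = True
        pred = np.zeros_like(gt)
        pred[4:8, 4:8, 5:9] = True  # overlap 48 of 64+64 -> d = 0.75
        pred[24:27, 24:27, 24:27] = True
        res = match_lesions(_mask(gt), _mask(pred))
        scores = lesionwise_scores(res)
        assert scores.lesionwise_dice == pytest.approx(0.75 / 2)

    def test_fp_contributes_full_hd95_penalty(self):
        gt = np.zeros((32, 32, 32), bool)
        gt[4:8, 4:8, 4:8] = True
        pred = gt.copy()
        pred[24:27, 24:27, 24:27] = True
        scores = lesionwise_scores(match_lesions(_mask(gt), _mask(pred)))
        # TP with hd95 0 plus FP penalty 374 over denominator 2
        assert scores.lesionwise_hd95 == pytest.approx(374.0 / 2)
        assert scores.lesionwise_dice == pytest.approx(1.0 / 2)

    def test_no_evaluable_lesions_is_vacuously_perfect(self):
        z = np.zeros((8, 8, 8), bool)
        scores = lesionwise_scores(match_lesions(_mask(z), _mask(z)))
        assert scores.lesionwise_dice == 1.0
        assert scores.lesionwise_hd95 == 0.0

    def test_all_penalty_limit(self):
        # every unit FN and every pred component FP -> hd95 pinned at 374
        gt = np.zeros((32, 32, 32), bool)
        gt[4:7, 4:7, 4:7] = True
        gt[14:17, 14:17, 14:17] = True
        pred = np.zeros_like(gt)
        pred[24:28, 24:28, 24:28] = True
        scores = lesionwise_scores(match_lesions(_mask(gt), _mask(pred)))
        assert scores.lesionwise_hd95 == pytest.approx(374.0)
        assert scores.lesionwise_dice == 0.0

    def test_adding_fp_decreases_dice_increases_hd95(self):
        gt = np.zeros((40, 40, 40), bool)
        gt[4:8, 4:8, 4:8] = True
        pred = gt.copy()
        s0 = lesionwise_scores(match_lesions(_mask(gt), _mask(pred)))
        pred_fp = pred.copy()
        pred_fp[30:33, 30:33, 30:33] = True
        s1 = lesionwise_scores(match_lesions(_mask(gt), _mask(pred_fp)))
        assert s1.lesionwise_dice < s0.lesionwise_dice
        assert s1.lesionwise_hd95 > s0.lesionwise_hd95

    def test_single_lesion_perfect_match_equals_legacy(self):
        gt = np.zeros((24, 24, 24), np.int16)
        gt[8:13, 8:13, 8:13] = 3
        lm = LabelMap(gt)
        scores = evaluate_case(lm, lm).regions["ET"]
        assert scores.lesionwise_dice == pytest.approx(scores.legacy_dice)
        assert scores.lesionwise_hd95 == pytest.approx(scores.legacy_hd95)


class TestEvaluateCase:
    def test_deleting_et_penalizes_only_affected_regions(self):
        gt = np.zeros((24, 24, 24), np.int16)
        gt[8:12, 8:12, 8:12] = 3
        gt[6:14, 6:14, 6:14][gt[6:14, 6:14, 6:14] == 0] = 2  # edema shell
        pred = gt.copy()
        pred[pred == 3] = 2  # ET missed entirely, WT support preserved
        scores = evaluate_case(LabelMap(gt), LabelMap(pred))
        assert scores.regions["ET"].lesionwise_dice == 0.0
        assert scores.regions["ET"].lesionwise_hd95 == 374.0
        assert scores.regions["WT"].lesionwise_dice == 1.0

    def test_counts_reported_per_region(self, rng):
        from lesionwise import PerturbationConfig, PhantomConfig, generate_phantom, perturb_prediction

        gt, manifest = generate_phantom(PhantomConfig(seed=11))
        pred, expected = perturb_prediction(gt, manifest, PerturbationConfig(seed=7))
        scores = evaluate_case(gt, pred)
        for region, want in expected["expected_counts"].items():
            got = scores.regions[region]
            assert (got.tp, got.fn, got.fp) == (want["TP"], want["FN"], want["FP"])


def _rec(vol, d, h=0.0, detected=True):
    return LesionRecord("c", "ET", 1, vol, d, h, detected)


class TestCohortAndCurves:
    def test_running_average_expanding_window(self):
        curve = running_average_by_volume([_rec(100, 1.0), _rec(10, 0.0)], "dice")
        np.testing.assert_allclose(curve, [[10, 0.0], [100, 0.5]])

    def test_ties_enter_together(self):
        curve = running_average_by_volume(
            [_rec(10, 0.0), _rec(10, 1.0), _rec(50, 1.0)], "dice"
        )
        np.testing.assert_allclose(curve, [[10, 0.5], [50, 2 / 3]])

    def test_all_detected_curve_is_flat_one(self):
        recs = [_rec(v, 1.0) for v in (5, 20, 80)]
        curve = running_average_by_volume(recs, "dice")
        np.testing.assert_allclose(curve[:, 1], 1.0)

    def test_empty_records_give_empty_curve(self):
        assert running_average_by_volume([], "dice").shape == (0, 2)

    def test_detection_curve_is_cumulative_fraction(self):
        recs = [_rec(10, 0.0, detected=False), _rec(20, 1.0), _rec(30, 1.0)]
        curve = running_average_by_volume(recs, "detected")
        np.testing.assert_allclose(curve[:, 1], [0.0, 0.5, 2 / 3])

    def test_exact_cohort_has_perfect_rates(self):
        gt = np.zeros((24, 24, 24), np.int16)
        gt[8:12, 8:12, 8:12] = 3
        lm = LabelMap(gt)
        cases = [evaluate_case(lm, lm, case_id=f"c{i}") for i in range(3)]
        summary = cohort_summary(cases)
        for region in ("ET", "TC", "WT"):
            assert summary.detection_rate[region] == 1.0
            assert summary.sensitivity[region] == 1.0
            assert summary.ppv[region] == 1.0

    def test_all_empty_predictions(self):
        gt = np.zeros((24, 24, 24), np.int16)
        gt[8:12, 8:12, 8:12] = 3
        empty = LabelMap(np.zeros_like(gt))
        cases = [evaluate_case(LabelMap(gt), empty, case_id=f"c{i}") for i in range(2)]
        with pytest.warns(UserWarning, match="PPV"):
            summary = cohort_summary(cases)
        assert summary.detection_rate["ET"] == 0.0
        assert summary.sensitivity["ET"] == 0.0
        assert summary.ppv["ET"] == 1.0

    def test_planted_counts_give_hand_computed_rates(self):
        # cohort with pooled TP=3, FN=1, FP=2 in ET
        gt1 = np.zeros((32, 32, 32), np.int16)
        gt1[4:8, 4:8, 4:8] = 3
        gt1[20:24, 20:24, 20:24] = 3
        pred1 = gt1.copy()
        pred1[20:24, 20:24, 20:24] = 0  # miss one
        pred1[4:7, 24:27, 24:27] = 3  # FP
        gt2 = np.zeros((32, 32, 32), np.int16)
        gt2[4:8, 4:8, 4:8] = 3
        gt2[20:24, 20:24, 20:24] = 3
        pred2 = gt2.copy()
        pred2[24:27, 4:7, 24:27] = 3  # FP
        cases = [
            evaluate_case(LabelMap(gt1), LabelMap(pred1), case_id="a"),
            evaluate_case(LabelMap(gt2), LabelMap(pred2), case_id="b"),
        ]
        summary = cohort_summary(cases)
        assert summary.detection_rate["ET"] == pytest.approx(3 / 4)
        assert summary.sensitivity["ET"] == pytest.approx((0.5 + 1.0) / 2)
        assert summary.ppv["ET"] == pytest.approx(3 / 5)

    def test_degenerate_cohort_rejected(self):
        empty = LabelMap(np.zeros((8, 8, 8), np.int16))
        cases = [evaluate_case(empty, empty, case_id="c")]
        with pytest.raises(DegenerateCohortError):
            cohort_summary(cases)
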