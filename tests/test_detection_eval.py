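"""Detection scoring: matching, AP, score_d, validity gate, diagnostics."""

import numpy as np
import pytest

from endoart.detection_eval import (BACKGROUND, confusion_matrix,
                                    average_precision, evaluate_detection,
                                    match_boxes, per_image_f1, validity_check)
from endoart.geometry_metrics import Box, box_iou
from endoart.io_formats import EAD_CATALOG, FrameAnnotations, SubmissionFrame
from endoart.synthetic_fixtures import (FixtureSpec, PerturbationSpec,
                                        generate_ground_truth,
                                        perturb_to_predictions)


def box(x1, y1, x2, y2, cls="specularity", conf=None):
    return Box(cls, x1, y1, x2, y2, confidence=conf)


def exhaustive_max_tp(refs, preds, thresh=0.25):
    """Brute-force maximum number of one-to-one matches at the threshold."""
    def rec(pi, used):
        if pi == len(preds):
            return 0
        best = rec(pi + 1, used)
        for ri in range(len(refs)):
            if ri not in used and box_iou(refs[ri], preds[pi]) >= thresh:
                best = max(best, 1 + rec(pi + 1, used | {ri}))
        return best
    return rec(0, frozenset())


class TestMatchBoxes:
    def test_single_pair(self):
        res = match_boxes([box(0, 0, 10, 10)], [box(0, 0, 10, 5, conf=0.7)])
        assert len(res.pairs) == 1
        assert not res.unmatched_refs and not res.unmatched_preds

    def test_higher_confidence_wins_contested_ref(self):
        refs = [box(0, 0, 10, 10)]
        preds = [box(0, 0, 10, 10, conf=0.9), box(1, 1, 11, 11, conf=0.5)]
        res = match_boxes(refs, preds)
        assert res.pairs[0][1].confidence == 0.9
        assert len(res.unmatched_preds) == 1

    def test_below_threshold_unmatched(self):
        res = match_boxes([box(0, 0, 10, 10)], [box(8, 8, 18, 18, conf=0.9)])
        assert not res.pairs
        assert len(res.unmatched_refs) == len(res.unmatched_preds) == 1

    def test_class_aware_blocks_cross_class(self):
        res = match_boxes([box(0, 0, 10, 10, "bubbles")],
                          [box(0, 0, 10, 10, "blur", conf=0.9)])
        assert not res.pairs
        res = match_boxes([box(0, 0, 10, 10, "bubbles")],
                          [box(0, 0, 10, 10, "blur", conf=0.9)], class_aware=False)
        assert len(res.pairs) == 1

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            match_boxes([], [], iou_thresh=1.5)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """tp count equals brute-force maximum assignment on small instances."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            refs = [box(*self._rand(rng)) for _ in range(rng.integers(1, 5))]
            preds = [box(*self._rand(rng), conf=float(rng.random()))
                     for _ in range(rng.integers(1, 5))]
            assert len(match_boxes(refs, preds).pairs) == exhaustive_max_tp(refs, preds)

    @staticmethod
    def _rand(rng):
        x1, y1 = rng.integers(0, 30, 2)
        w, h = rng.integers(2, 20, 2)
        return float(x1), float(y1), float(x1 + w), float(y1 + h)

    def test_lower_threshold_never_loses_matches(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            refs = [box(*self._rand(rng)) for _ in range(rng.integers(1, 4))]
            preds = [box(*self._rand(rng), conf=float(rng.random()))
                     for _ in range(rng.integers(1, 4))]
            tps = [len(match_boxes(refs, preds, iou_thresh=t).pairs)
                   for t in (0.6, 0.4, 0.25, 0.1)]
            assert tps == sorted(tps)


class TestAveragePrecision:
    def _frames(self, preds):
        gt = {"f0": FrameAnnotations("f0", boxes=[box(0, 0, 10, 10)])}
        sub = {"f0": SubmissionFrame("f0", boxes=preds)}
        return gt, sub

    def test_perfect_retrieval(self):
        gt, sub = self._frames([box(0, 0, 10, 10, conf=0.3)])
        assert average_precision(gt, sub, "specularity") == 1.0

    def test_false_positive_ranked_first(self):
        """High-confidence miss then a hit: PR points (0,0), (0.5,1) -> AP 0.5."""
        gt, sub = self._frames([box(30, 30, 40, 40, conf=0.9),
                                box(0, 0, 10, 10, conf=0.5)])
        assert average_precision(gt, sub, "specularity") == pytest.approx(0.5)

    def test_no_predictions(self):
        gt, sub = self._frames([])
        assert average_precision(gt, sub, "specularity") == 0.0

    def test_no_references_is_undefined(self):
        gt, sub = self._frames([box(0, 0, 10, 10, conf=0.9)])
        assert average_precision(gt, sub, "bubbles") is None

    def test_three_prediction_hand_integration(self):
        """2 refs; ranked hit, miss, hit -> precisions 1, 1/2, 2/3; AP = 5/6.

        With the monotone envelope, recall steps 0->1/2 at precision 1 and
        1/2->1 at precision 2/3: AP = 1/2 + (1/2)(2/3) = 5/6.
        """
        gt = {"f0": FrameAnnotations("f0", boxes=[box(0, 0, 10, 10),
                                                  box(40, 40, 50, 50)])}
        sub = {"f0": SubmissionFrame("f0", boxes=[
            box(0, 0, 10, 10, conf=0.9),
            box(70, 70, 80, 80, conf=0.6),
            box(40, 40, 50, 50, conf=0.4),
        ])}
        assert average_precision(gt, sub, "specularity") == pytest.approx(5 / 6)

    def test_rank_only_dependence_on_confidence(self):
        gt = {"f0": FrameAnnotations("f0", boxes=[box(0, 0, 10, 10),
                                                  box(40, 40, 50, 50)])}
        def sub(scale):
            return {"f0": SubmissionFrame("f0", boxes=[
                box(0, 0, 10, 10, conf=0.8 * scale),
                box(70, 70, 80, 80, conf=0.6 * scale),
                box(40, 40, 50, 50, conf=0.4 * scale),
            ])}
        assert average_precision(gt, sub(1.0), "specularity") == \
            average_precision(gt, sub(0.5), "specularity")


class TestEvaluateDetection:
    def test_perfect_submission_scores_one(self, small_gt, perfect_sub):
        card = evaluate_detection(small_gt, perfect_sub)
        assert card.mAP == pytest.approx(1.0)
        assert card.mean_iou == pytest.approx(1.0)
        assert card.score_d == pytest.approx(1.0)
        assert card.valid

    def test_score_d_weighting_identity(self, small_gt):
        noisy = perturb_to_predictions(
            small_gt, PerturbationSpec(loc_noise_sd=5, drop_prob=0.2, seed=3))
        card = evaluate_detection(small_gt, noisy)
        assert card.score_d == pytest.approx(0.6 * card.mAP + 0.4 * card.mean_iou,
                                             abs=1e-12)

    def test_absent_classes_excluded_from_means(self, single_frame_pair):
        gt, sub = single_frame_pair
        card = evaluate_detection(gt, sub)
        assert card.per_class_ap["blur"] is None
        scored = [c for c, v in card.per_class_ap.items() if v is not None]
        assert set(scored) == {"specularity", "bubbles"}

    def test_missing_frame_scored_as_empty(self, small_gt, perfect_sub):
        partial = {k: v for k, v in perfect_sub.items() if k != "frame_00000"}
        card = evaluate_detection(small_gt, partial)
        assert card.mAP < 1.0

    def test_empty_ground_truth_rejected(self):
        gt = {"f0": FrameAnnotations("f0", boxes=[])}
        with pytest.raises(ValueError):
            evaluate_detection(gt, {"f0": SubmissionFrame("f0")})


class TestValidityCheck:
    @pytest.mark.parametrize("m, i, valid, ratio", [
        (0.3235, 0.4172, True, 1.2897),   # just under the 1.3 gate
        (0.3, 0.5, False, 5 / 3),
        (0.4, 0.4, True, 1.0),
        (0.3, 0.21, False, 0.7),          # boundary is strict
        (0.3, 0.39, False, 1.3),
    ])
    def test_gate(self, m, i, valid, ratio):
        ok, r = validity_check(m, i)
        assert ok is valid
        assert r == pytest.approx(ratio, abs=1e-4)

    def test_zero_map_invalid(self):
        ok, r = validity_check(0.0, 0.2)
        assert not ok and np.isnan(r)


class TestConfusionMatrix:
    def test_wrong_class_right_geometry(self):
        gt = {"f0": FrameAnnotations("f0", boxes=[box(0, 0, 10, 10, "bubbles")])}
        sub = {"f0": SubmissionFrame("f0", boxes=[box(0, 0, 10, 10, "blur", conf=0.9)])}
        cm = confusion_matrix(gt, sub)
        assert cm.loc["bubbles", "blur"] == 1
        assert cm.to_numpy().sum() == 1

    def test_perfect_submission_is_diagonal(self, small_gt, perfect_sub):
        cm = confusion_matrix(small_gt, perfect_sub)
        off = cm.to_numpy().sum() - np.trace(cm.to_numpy())
        assert off == 0

    def test_no_predictions_all_background(self, small_gt):
        empty = {f: SubmissionFrame(f) for f in small_gt}
        cm = confusion_matrix(small_gt, empty)
        n_gt = sum(len(a.boxes) for a in small_gt.values())
        assert cm[BACKGROUND].sum() == n_gt
        assert cm.loc[BACKGROUND].sum() == 0

    def test_row_sums_equal_reference_counts(self, small_gt):
        noisy = perturb_to_predictions(
            small_gt, PerturbationSpec(loc_noise_sd=6, mislabel_prob=0.3,
                                       spurious_rate=1.0, seed=5))
        cm = confusion_matrix(small_gt, noisy)
        for cls in EAD_CATALOG.detection_classes:
            n_ref = sum(1 for a in small_gt.values()
                        for b in a.boxes if b.class_label == cls)
            assert cm.loc[cls].sum() == n_ref


class TestPerImageF1:
    def test_perfect_frame(self, small_gt, perfect_sub):
        scores = per_image_f1(small_gt, perfect_sub)
        assert all(v == pytest.approx(1.0) for v in scores.values())

    def test_no_predictions_zero(self, single_frame_pair):
        gt, _ = single_frame_pair
        scores = per_image_f1(gt, {"f0": SubmissionFrame("f0")})
        assert scores["f0"] == 0.0

    def test_half_matched(self):
        gt = {"f0": FrameAnnotations("f0", boxes=[box(0, 0, 10, 10),
                                                  box(40, 40, 50, 50)])}
        sub = {"f0": SubmissionFrame("f0", boxes=[
            box(0, 0, 10, 10, conf=0.9), box(70, 70, 80, 80, conf=0.5)])}
        assert per_image_f1(gt, sub)["f0"] == pytest.approx(0.5)
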