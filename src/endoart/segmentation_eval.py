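"""Semantic segmentation scoring and the composite s-score.

Each frame is scored per class with pixel-level Dice (DSC), Jaccard (J),
their arithmetic mean ("overlap"), F2, positive predictive value (pixel
precision) and recall.  Averaging is macro-macro: per-frame per-class values
are averaged over frames, then over the segmentation classes.  The
leaderboard score is computed from the aggregate values:

    score_s = 0.75 * [0.5 * (F1 + J)] + 0.25 * F2,   F1 = aggregate DSC

which sits between F1 and F2 and so places a moderate extra weight on
recall.  A class empty in both reference and prediction scores 1 for the
frame (agreement on absence); empty-reference-vs-nonempty-prediction (and
vice versa) scores 0.  Because real endoscopy masks are mostly background,
this convention lets an all-background prediction earn a nonzero s-score —
the pixel-imbalance caveat the leaderboard itself carries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple

import numpy as np

from .geometry_metrics import (EMPTY_EMPTY_SCORE, f_beta, mask_counts,
                               mask_dsc, mask_jaccard, precision_recall)
from .io_formats import EAD_CATALOG, ClassCatalog, FrameAnnotations, SubmissionFrame

__all__ = ["ClassMaskMetrics", "SegScorecard", "evaluate_class_mask",
           "aggregate_segmentation", "segmentation_score"]


class ClassMaskMetrics(NamedTuple):
    dsc: float
    jaccard: float
    overlap: float
    f2: float
    ppv: float
    recall: float


@dataclass
class SegScorecard:
    per_class: Dict[str, ClassMaskMetrics]
    aggregate: ClassMaskMetrics
    s_score: float


def segmentation_score(f1: float, jaccard: float, f2: float) -> float:
    """score_s = 0.75·[0.5·(F1 + J)] + 0.25·F2."""
    return 0.75 * (0.5 * (f1 + jaccard)) + 0.25 * f2


def evaluate_class_mask(r: np.ndarray, s: np.ndarray,
                        empty_value: float = EMPTY_EMPTY_SCORE) -> ClassMaskMetrics:
    """Per-class pixel metrics for one frame (reference mask r, prediction s)."""
    c = mask_counts(r, s)
    dsc = mask_dsc(r, s, empty_value)
    j = mask_jaccard(r, s, empty_value)
    ppv, rec = precision_recall(c, empty_value)
    if c.n_gt == 0 and c.n_pred == 0:
        f2 = empty_value
    else:
        f2 = f_beta(ppv if c.n_pred else 0.0, rec if c.n_gt else 0.0, beta=2.0)
    return ClassMaskMetrics(dsc=dsc, jaccard=j, overlap=0.5 * (dsc + j),
                            f2=f2, ppv=ppv, recall=rec)


def aggregate_segmentation(gt: Mapping[str, FrameAnnotations],
                           sub: Mapping[str, SubmissionFrame],
                           catalog: ClassCatalog = EAD_CATALOG,
                           empty_value: float = EMPTY_EMPTY_SCORE) -> SegScorecard:
    """Macro-macro segmentation scorecard over frames and classes.

    A frame missing from the submission is scored against all-zero
    prediction masks.  The s-score is computed from the aggregate F1
    (= mean DSC), Jaccard and F2, matching the leaderboard identity
    s = 0.75·[0.5·(F1+J)] + 0.25·F2.
    """
    if not gt:
        raise ValueError("no ground-truth frames")
    per_class_frames: Dict[str, list] = {c: [] for c in catalog.segmentation_classes}
    for fid in sorted(gt):
        ann = gt[fid]
        frame = sub.get(fid)
        shape = None
        for m in ann.masks.values():
            shape = np.asarray(m).shape
            break
        if shape is None:
            raise ValueError(f"frame {fid} has no ground-truth masks")
        for cls in catalog.segmentation_classes:
            r = np.asarray(ann.masks.get(cls, np.zeros(shape, dtype=np.uint8)))
            if frame is not None and cls in frame.masks:
                s = np.asarray(frame.masks[cls])
            else:
                s = np.zeros(shape, dtype=np.uint8)
            per_class_frames[cls].append(evaluate_class_mask(r, s, empty_value))

    per_class = {
        cls: ClassMaskMetrics(*np.mean(np.array(vals), axis=0))
        for cls, vals in per_class_frames.items()
    }
    aggregate = ClassMaskMetrics(*np.mean(np.array(list(per_class.values())), axis=0))
    s = segmentation_score(aggregate.dsc, aggregate.jaccard, aggregate.f2)
    return SegScorecard(per_class=per_class, aggregate=aggregate, s_score=s)
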