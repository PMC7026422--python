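"""Detection scoring: box matching, average precision, score_d and diagnostics.

A prediction matches a reference box when their IoU is at least the match
threshold (0.25 by default, deliberately permissive so that coarse
localisation of artefacts is rewarded).  Matching is greedy in descending
prediction confidence; ties in confidence are broken by input order, ties in
IoU by reference order, which makes every score deterministic for a given
submission file.

The leaderboard score is ``score_d = 0.6 mAP + 0.4 IoU``, weighting mean
average precision above localisation tightness to favour retrieval of all
artefacts.  Submissions are additionally gated on the IoU/mAP ratio
(0.7 < ratio < 1.3): a large imbalance between the two indicates score
gaming rather than genuine detection quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .geometry_metrics import Box, CountTriple, box_iou, f_beta
from .io_formats import EAD_CATALOG, ClassCatalog, FrameAnnotations, SubmissionFrame

__all__ = [
    "MatchResult",
    "DetectionScorecard",
    "match_boxes",
    "average_precision",
    "evaluate_detection",
    "validity_check",
    "confusion_matrix",
    "per_image_f1",
    "BACKGROUND",
]

#: Label used for the unmatched row/column of the confusion matrix.
BACKGROUND = "__background__"


@dataclass
class MatchResult:
    pairs: List[Tuple[Box, Box, float]]
    unmatched_refs: List[Box]
    unmatched_preds: List[Box]

    @property
    def counts(self) -> CountTriple:
        tp = len(self.pairs)
        return CountTriple(tp=tp, n_pred=tp + len(self.unmatched_preds),
                           n_gt=tp + len(self.unmatched_refs))


@dataclass
class DetectionScorecard:
    """Per-class and aggregate detection scores for one submission.

    ``per_class_ap`` maps a class to its average precision, or ``None`` for
    classes with no reference boxes (excluded from the mAP mean).
    ``mean_iou_pooled`` is the secondary pooled-over-boxes aggregate; the
    macro (per-class) mean is primary and feeds ``score_d``.
    """

    per_class_ap: Dict[str, Optional[float]]
    per_class_iou: Dict[str, Optional[float]]
    mAP: float
    mean_iou: float
    score_d: float
    valid: bool
    validity_ratio: float
    mean_iou_pooled: float = float("nan")


def _confidence_order(preds: Sequence[Box]) -> List[int]:
    # stable sort: equal confidences keep input order
    return sorted(range(len(preds)), key=lambda i: -(preds[i].confidence or 0.0))


def match_boxes(refs: Sequence[Box], preds: Sequence[Box], iou_thresh: float = 0.25,
                class_aware: bool = True) -> MatchResult:
    """One-to-one assignment of predictions to reference boxes.

    Predictions are seated in descending confidence; each tries the
    still-unmatched reference (same class when ``class_aware``) with the
    highest IoU >= ``iou_thresh``, and may re-seat an earlier prediction
    onto its next-best eligible reference (augmenting-path search) so that
    the final matching has maximum cardinality.  Higher-confidence
    predictions keep priority over contested references; ties in confidence
    are broken by input order and ties in IoU by reference order, so the
    result is deterministic.
    """
    if not (0.0 < iou_thresh < 1.0):
        raise ValueError(f"iou_thresh must lie in (0, 1), got {iou_thresh}")
    # eligible refs per prediction, best IoU first
    eligible: List[List[Tuple[float, int]]] = []
    for pred in preds:
        cand = []
        for j, ref in enumerate(refs):
            if class_aware and ref.class_label != pred.class_label:
                continue
            iou = box_iou(ref, pred)
            if iou >= iou_thresh:
                cand.append((iou, j))
        cand.sort(key=lambda t: (-t[0], t[1]))
        eligible.append(cand)

    ref_owner = [-1] * len(refs)   # pred index currently seated on each ref
    pred_seat = [-1] * len(preds)  # ref index each pred is seated on

    def try_seat(pi: int, visited: set) -> bool:
        for _, j in eligible[pi]:
            if j in visited:
                continue
            visited.add(j)
            if ref_owner[j] < 0 or try_seat(ref_owner[j], visited):
                ref_owner[j] = pi
                pred_seat[pi] = j
                return True
        return False

    for pi in _confidence_order(preds):
        try_seat(pi, set())

    pairs = [(refs[j], preds[pi], box_iou(refs[j], preds[pi]))
             for pi, j in enumerate(pred_seat) if j >= 0]
    unmatched_refs = [r for j, r in enumerate(refs) if ref_owner[j] < 0]
    unmatched_preds = [p for i, p in enumerate(preds) if pred_seat[i] < 0]
    return MatchResult(pairs=pairs, unmatched_refs=unmatched_refs,
                       unmatched_preds=unmatched_preds)


def average_precision(gt: Mapping[str, FrameAnnotations],
                      sub: Mapping[str, SubmissionFrame],
                      class_label: str, iou_thresh: float = 0.25) -> Optional[float]:
    """All-point area under the precision-recall curve for one class.

    Predictions of the class are pooled over frames, ranked by decreasing
    confidence, and matched greedily within their frame.  Precision is
    interpolated to its monotone envelope before integrating over recall
    (the modern all-point AP; no 11-point sampling).  Returns ``None`` when
    the class has no reference boxes anywhere (AP undefined).
    """
    n_gt = sum(1 for ann in gt.values() for b in ann.boxes if b.class_label == class_label)
    if n_gt == 0:
        return None
    # (confidence, frame order, line order) keeps ties deterministic
    records = []
    for order, fid in enumerate(sorted(gt)):
        frame = sub.get(fid)
        if frame is None:
            continue
        for k, b in enumerate(frame.boxes):
            if b.class_label == class_label:
                records.append((-(b.confidence or 0.0), order, k, fid, b))
    records.sort(key=lambda t: (t[0], t[1], t[2]))
    if not records:
        return 0.0

    taken: Dict[str, list] = {}
    tp_flags = np.zeros(len(records), dtype=bool)
    for i, (_, _, _, fid, pred) in enumerate(records):
        refs = [b for b in gt[fid].boxes if b.class_label == class_label]
        if fid not in taken:
            taken[fid] = [False] * len(refs)
        best_j, best_iou = -1, 0.0
        for j, ref in enumerate(refs):
            if taken[fid][j]:
                continue
            iou = box_iou(ref, pred)
            if iou >= iou_thresh and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0:
            taken[fid][best_j] = True
            tp_flags[i] = True

    tp_cum = np.cumsum(tp_flags)
    precision = tp_cum / np.arange(1, len(records) + 1)
    recall = tp_cum / n_gt
    # monotone precision envelope, integrate over recall steps
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(precision, recall):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def validity_check(mAP: float, mean_iou: float,
                   lo: float = 0.7, hi: float = 1.3) -> Tuple[bool, float]:
    """IoU/mAP ratio gate: valid iff ``lo < mean_iou/mAP < hi`` (strict)."""
    if mAP <= 0:
        return False, float("nan")
    ratio = mean_iou / mAP
    return (lo < ratio < hi), ratio


def _per_class_iou(gt: Mapping[str, FrameAnnotations],
                   sub: Mapping[str, SubmissionFrame],
                   catalog: ClassCatalog, iou_thresh: float) -> Tuple[Dict[str, Optional[float]], float]:
    """Per-class mean best-match IoU per reference box; unmatched refs count 0.

    Returns the per-class map and the pooled-over-all-boxes mean.
    """
    per_class_vals: Dict[str, list] = {c: [] for c in catalog.detection_classes}
    for fid in sorted(gt):
        ann = gt[fid]
        frame = sub.get(fid)
        preds = frame.boxes if frame is not None else []
        res = match_boxes(ann.boxes, preds, iou_thresh=iou_thresh, class_aware=True)
        matched = {id(ref): iou for ref, _, iou in res.pairs}
        for ref in ann.boxes:
            per_class_vals[ref.class_label].append(matched.get(id(ref), 0.0))
    per_class: Dict[str, Optional[float]] = {}
    pooled: List[float] = []
    for c, vals in per_class_vals.items():
        per_class[c] = float(np.mean(vals)) if vals else None
        pooled.extend(vals)
    pooled_mean = float(np.mean(pooled)) if pooled else float("nan")
    return per_class, pooled_mean


def evaluate_detection(gt: Mapping[str, FrameAnnotations],
                       sub: Mapping[str, SubmissionFrame],
                       catalog: ClassCatalog = EAD_CATALOG,
                       iou_thresh: float = 0.25) -> DetectionScorecard:
    """Full detection scorecard: per-class AP/IoU, mAP, mean IoU, score_d, gate.

    Macro means are taken over classes that have at least one reference box;
    classes absent from the ground truth are reported as ``None`` and do not
    distort small fixtures.
    """
    if not any(ann.boxes for ann in gt.values()):
        raise ValueError("ground truth contains no boxes in any frame")
    per_class_ap = {
        c: average_precision(gt, sub, c, iou_thresh) for c in catalog.detection_classes
    }
    per_class_iou, pooled_iou = _per_class_iou(gt, sub, catalog, iou_thresh)
    ap_vals = [v for v in per_class_ap.values() if v is not None]
    iou_vals = [v for v in per_class_iou.values() if v is not None]
    mAP = float(np.mean(ap_vals))
    mean_iou = float(np.mean(iou_vals))
    score_d = 0.6 * mAP + 0.4 * mean_iou
    valid, ratio = validity_check(mAP, mean_iou)
    return DetectionScorecard(per_class_ap=per_class_ap, per_class_iou=per_class_iou,
                              mAP=mAP, mean_iou=mean_iou, score_d=score_d,
                              valid=valid, validity_ratio=ratio,
                              mean_iou_pooled=pooled_iou)


def confusion_matrix(gt: Mapping[str, FrameAnnotations],
                     sub: Mapping[str, SubmissionFrame],
                     catalog: ClassCatalog = EAD_CATALOG,
                     iou_thresh: float = 0.25) -> "pd.DataFrame":
    """Class confusion counts from class-agnostic geometric matching.

    Cell (ref class, pred class) counts reference boxes whose geometrically
    assigned prediction carries that class; the background column holds
    unassigned references and the background row unassigned predictions.
    Row sums over reference classes equal the reference box counts.
    """
    import pandas as pd

    labels = list(catalog.detection_classes)
    idx = labels + [BACKGROUND]
    counts = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
    for fid in sorted(gt):
        ann = gt[fid]
        frame = sub.get(fid)
        preds = frame.boxes if frame is not None else []
        res = match_boxes(ann.boxes, preds, iou_thresh=iou_thresh, class_aware=False)
        for ref, pred, _ in res.pairs:
            counts.loc[ref.class_label, pred.class_label] += 1
        for ref in res.unmatched_refs:
            counts.loc[ref.class_label, BACKGROUND] += 1
        for pred in res.unmatched_preds:
            counts.loc[BACKGROUND, pred.class_label] += 1
    return counts


def per_image_f1(gt: Mapping[str, FrameAnnotations],
                 sub: Mapping[str, SubmissionFrame],
                 iou_thresh: float = 0.25) -> Dict[str, float]:
    """Per-frame F1 from class-aware matching pooled over classes."""
    out: Dict[str, float] = {}
    for fid in sorted(gt):
        ann = gt[fid]
        frame = sub.get(fid)
        preds = frame.boxes if frame is not None else []
        c = match_boxes(ann.boxes, preds, iou_thresh=iou_thresh, class_aware=True).counts
        if c.n_gt == 0 and c.n_pred == 0:
            out[fid] = 1.0
            continue
        p = c.tp / c.n_pred if c.n_pred else 0.0
        r = c.tp / c.n_gt if c.n_gt else 0.0
        out[fid] = f_beta(p, r, 1.0)
    return out
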