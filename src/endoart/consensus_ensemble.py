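"""Consensus "Merged" super-detector and super-segmenter.

Boxes from all submissions are clustered per class by single-linkage on
pairwise IoU; a cluster supported by more than ``min_fraction`` of the
submissions (strict majority by default) survives, represented by its
highest-confidence member box.  A submission's duplicate boxes count once
towards a cluster's support.  Mask consensus is a per-pixel vote: a pixel
is foreground when more than ``min_fraction`` of submissions mark it so.

The contribution tally attributes each surviving representative box (or
each consensus pixel) to the submission that supplied it, which shows
whether the merged predictor draws on one dominant team or on a mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .geometry_metrics import Box, box_iou
from .io_formats import SubmissionFrame

__all__ = ["ConsensusConfig", "merge_detections", "merge_segmentations",
           "contribution_tally", "contribution_tally_masks"]


@dataclass(frozen=True)
class ConsensusConfig:
    min_fraction: float = 0.5   # strict: support must exceed this fraction
    iou_thresh: float = 0.25
    # "single" links any two boxes with IoU >= thresh transitively;
    # "greedy-first" matches each box against the first cluster member only
    linkage: str = "single"

    def __post_init__(self) -> None:
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must lie in (0, 1]")
        if not (0.0 < self.iou_thresh < 1.0):
            raise ValueError("iou_thresh must lie in (0, 1)")
        if self.linkage not in ("single", "greedy-first"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _cluster(items: List[Tuple[int, Box]], cfg: ConsensusConfig) -> List[List[Tuple[int, Box]]]:
    n = len(items)
    if cfg.linkage == "single":
        uf = _UnionFind(n)
        for i in range(n):
            for j in range(i + 1, n):
                if box_iou(items[i][1], items[j][1]) >= cfg.iou_thresh:
                    uf.union(i, j)
        groups: Dict[int, List[Tuple[int, Box]]] = {}
        for i in range(n):
            groups.setdefault(uf.find(i), []).append(items[i])
        return [groups[k] for k in sorted(groups)]
    # greedy-first: compare against each cluster's founding box only
    clusters: List[List[Tuple[int, Box]]] = []
    for item in items:
        for cl in clusters:
            if box_iou(cl[0][1], item[1]) >= cfg.iou_thresh:
                cl.append(item)
                break
        else:
            clusters.append([item])
    return clusters


def merge_detections(subs: Sequence[SubmissionFrame],
                     cfg: ConsensusConfig = ConsensusConfig()) -> SubmissionFrame:
    """Build the consensus frame from >= 2 submissions for the same frame.

    Returns a :class:`SubmissionFrame` whose boxes are the representative
    (highest-confidence, ties broken by submission then box order) members
    of clusters supported by a strict majority of submissions.
    """
    if len(subs) < 2:
        raise ValueError("consensus needs at least two submissions")
    frame_id = subs[0].frame_id
    n = len(subs)
    merged: List[Box] = []
    classes: List[str] = []
    for sub in subs:
        for b in sub.boxes:
            if b.class_label not in classes:
                classes.append(b.class_label)
    for cls in classes:
        items = [(si, b) for si, sub in enumerate(subs)
                 for b in sub.boxes if b.class_label == cls]
        for cluster in _cluster(items, cfg):
            support = len({si for si, _ in cluster})
            if support / n <= cfg.min_fraction:
                continue
            rep = max(cluster, key=lambda t: ((t[1].confidence or 0.0), -t[0]))
            merged.append(rep[1])
    return SubmissionFrame(frame_id=frame_id, boxes=merged)


def merge_segmentations(mask_sets: Sequence[Mapping[str, np.ndarray]],
                        cfg: ConsensusConfig = ConsensusConfig()) -> Dict[str, np.ndarray]:
    """Per-pixel majority vote over >= 2 per-class mask sets."""
    if len(mask_sets) < 2:
        raise ValueError("consensus needs at least two submissions")
    n = len(mask_sets)
    classes: List[str] = []
    for ms in mask_sets:
        for cls in ms:
            if cls not in classes:
                classes.append(cls)
    out: Dict[str, np.ndarray] = {}
    for cls in classes:
        stack = None
        shape = None
        votes = None
        for ms in mask_sets:
            if cls not in ms:
                continue
            m = np.asarray(ms[cls]) > 0
            if shape is None:
                shape = m.shape
                votes = np.zeros(shape, dtype=np.int32)
            elif m.shape != shape:
                raise ValueError(f"mask shape mismatch for class {cls!r}: {m.shape} vs {shape}")
            votes += m
        out[cls] = (votes / n > cfg.min_fraction).astype(np.uint8)
    return out


def contribution_tally(subs: Sequence[SubmissionFrame], merged: SubmissionFrame) -> Dict[int, int]:
    """Count merged representative boxes supplied by each submission index.

    A representative identical across submissions is credited to the
    earliest submission containing it (ties in confidence broken by
    submission order, as in :func:`merge_detections`).
    """
    counts = {i: 0 for i in range(len(subs))}
    for box in merged.boxes:
        for si, sub in enumerate(subs):
            if any(b == box for b in sub.boxes):
                counts[si] += 1
                break
    return counts


def contribution_tally_masks(mask_sets: Sequence[Mapping[str, np.ndarray]],
                             merged: Mapping[str, np.ndarray]) -> Dict[int, int]:
    """Count consensus foreground pixels each submission voted for."""
    counts = {i: 0 for i in range(len(mask_sets))}
    for cls, cons in merged.items():
        cons = np.asarray(cons) > 0
        for si, ms in enumerate(mask_sets):
            if cls in ms:
                counts[si] += int(np.count_nonzero((np.asarray(ms[cls]) > 0) & cons))
    return counts
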