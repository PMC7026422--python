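"""Primitive overlap and retrieval metrics shared by all evaluators.

Boxes follow a half-open pixel convention: a box ``(x1, y1, x2, y2)`` covers
columns ``x1 <= x < x2`` and rows ``y1 <= y < y2``, so its area is
``(x2 - x1) * (y2 - y1)``.  This makes box IoU agree exactly with the mask
Jaccard of the two boxes rasterised onto a pixel grid.

Empty-vs-empty convention
-------------------------
When a class is absent from both the reference and the prediction, the
per-class overlap scores (Jaccard, Dice, precision, recall) for that frame
are defined as 1 — perfect agreement on absence.  An empty reference against
a non-empty prediction (or vice versa) scores 0.  The convention is exposed
as the ``empty_value`` argument everywhere it applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Box",
    "CountTriple",
    "box_iou",
    "box_area",
    "mask_jaccard",
    "mask_dsc",
    "mask_counts",
    "precision_recall",
    "f_beta",
    "rasterize_box",
]

#: Score assigned when both reference and prediction are empty.
EMPTY_EMPTY_SCORE = 1.0


@dataclass(frozen=True)
class Box:
    """A rectangular region with a class label and optional confidence.

    Coordinates are 0-based pixels, half-open: ``x2 > x1`` and ``y2 > y1``.
    Reference (ground-truth) boxes carry ``confidence=None``.
    """

    class_label: str
    x1: float
    y1: float
    x2: float
    y2: float
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        for v in (self.x1, self.y1, self.x2, self.y2):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"box coordinates must be finite and >= 0, got {self}")
        if self.x2 <= self.x1 or self.y2 <= self.y1:
            raise ValueError(f"degenerate box: ({self.x1}, {self.y1}, {self.x2}, {self.y2})")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence outside [0, 1]: {self.confidence}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)


@dataclass(frozen=True)
class CountTriple:
    """True-positive / predicted / reference instance counts."""

    tp: int
    n_pred: int
    n_gt: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.n_pred < 0 or self.n_gt < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp > self.n_pred or self.tp > self.n_gt:
            raise ValueError("tp cannot exceed n_pred or n_gt")


def box_area(box: Box) -> float:
    return box.area


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 iff identical."""
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def _as_binary(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    return m > 0


def mask_counts(r: np.ndarray, s: np.ndarray) -> CountTriple:
    """Pixel counts (tp, |S|, |R|) for a reference/prediction mask pair."""
    r = _as_binary(r)
    s = _as_binary(s)
    if r.shape != s.shape:
        raise ValueError(f"mask shape mismatch: {r.shape} vs {s.shape}")
    tp = int(np.count_nonzero(r & s))
    return CountTriple(tp=tp, n_pred=int(np.count_nonzero(s)), n_gt=int(np.count_nonzero(r)))


def mask_jaccard(r: np.ndarray, s: np.ndarray, empty_value: float = EMPTY_EMPTY_SCORE) -> float:
    """Jaccard index |R∩S| / |R∪S| over foreground pixels."""
    r = _as_binary(r)
    s = _as_binary(s)
    if r.shape != s.shape:
        raise ValueError(f"mask shape mismatch: {r.shape} vs {s.shape}")
    inter = int(np.count_nonzero(r & s))
    union = int(np.count_nonzero(r | s))
    if union == 0:
        return empty_value
    return inter / union


def mask_dsc(r: np.ndarray, s: np.ndarray, empty_value: float = EMPTY_EMPTY_SCORE) -> float:
    """Dice similarity coefficient 2|R∩S| / (|R|+|S|).

    Satisfies DSC = 2 J / (1 + J) for the same mask pair.
    """
    c = mask_counts(r, s)
    denom = c.n_gt + c.n_pred
    if denom == 0:
        return empty_value
    return 2.0 * c.tp / denom


def precision_recall(c: CountTriple, empty_value: float = EMPTY_EMPTY_SCORE) -> tuple[float, float]:
    """(precision, recall) = (tp/n_pred, tp/n_gt), with 0/0 -> ``empty_value``."""
    p = c.tp / c.n_pred if c.n_pred > 0 else empty_value
    r = c.tp / c.n_gt if c.n_gt > 0 else empty_value
    return p, r


def f_beta(p: float, r: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean (1+β²)·p·r / (β²·p + r); 0 when p = r = 0."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * beta * p + r
    if denom == 0:
        return 0.0
    return (1.0 + beta * beta) * p * r / denom


def rasterize_box(box: Box, height: int, width: int) -> np.ndarray:
    """Paint a box onto a zero grid under the half-open convention."""
    grid = np.zeros((height, width), dtype=np.uint8)
    x1 = max(0, int(math.floor(box.x1)))
    y1 = max(0, int(math.floor(box.y1)))
    x2 = min(width, int(math.ceil(box.x2)))
    y2 = min(height, int(math.ceil(box.y2)))
    if x2 > x1 and y2 > y1:
        grid[y1:y2, x1:x2] = 1
    return grid
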