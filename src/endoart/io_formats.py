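"""Reading and writing annotations, submissions and mask images.

File dialects
-------------
* Detection / generalization submissions: one plain-text file per frame,
  named ``<frame_id>.txt``, one box per whitespace-separated line::

      <class_name> <confidence> <x1> <y1> <x2> <y2>

  Ground-truth box files use the same dialect without the confidence column
  (``<class_name> <x1> <y1> <x2> <y2>``).
* Segmentation masks: one single-channel PNG per class per frame, named
  ``<frame_id>_<class>.png``; any pixel value > 0 counts as foreground, so
  both {0, 1} and {0, 255} dialects are accepted.
* A frame present in the ground truth but missing from a submission is
  scored as an empty prediction (no boxes / all-zero masks); this keeps the
  scoring denominators fixed across submissions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import yaml
from PIL import Image

from .geometry_metrics import Box

logger = logging.getLogger(__name__)

__all__ = [
    "ClassCatalog",
    "FrameAnnotations",
    "SubmissionFrame",
    "EAD_CATALOG",
    "read_detection_file",
    "write_detection_file",
    "read_gt_box_file",
    "write_gt_box_file",
    "read_mask_set",
    "write_mask_set",
    "read_submission_dir",
    "read_gt_dir",
    "validate_submission",
    "load_config",
]


class FormatError(ValueError):
    """Raised when a submission or annotation file does not parse."""


@dataclass(frozen=True)
class ClassCatalog:
    """Ordered class identifiers for detection and segmentation scope.

    ``segmentation_classes`` must be a subset of ``detection_classes``;
    ``n_detection`` is the N that normalises the mean generalization
    deviation.
    """

    detection_classes: tuple
    segmentation_classes: tuple

    def __post_init__(self) -> None:
        if len(set(self.detection_classes)) != len(self.detection_classes):
            raise ValueError("duplicate detection class names")
        missing = set(self.segmentation_classes) - set(self.detection_classes)
        if missing:
            raise ValueError(f"segmentation classes not in detection set: {sorted(missing)}")

    @property
    def names(self) -> tuple:
        return self.detection_classes

    @property
    def n_detection(self) -> int:
        return len(self.detection_classes)

    @property
    def n_segmentation(self) -> int:
        return len(self.segmentation_classes)


#: The seven endoscopy artefact classes; masks exist for five of them
#: (blur and contrast are box-only).
EAD_CATALOG = ClassCatalog(
    detection_classes=(
        "specularity",
        "saturation",
        "artefact",
        "blur",
        "contrast",
        "bubbles",
        "instrument",
    ),
    segmentation_classes=(
        "specularity",
        "saturation",
        "artefact",
        "bubbles",
        "instrument",
    ),
)


@dataclass
class FrameAnnotations:
    """Ground-truth boxes and per-class masks for one frame.

    The same spatial location may carry several class labels; overlapping
    boxes and masks of different classes are expected, not an error.
    """

    frame_id: str
    boxes: List[Box] = field(default_factory=list)
    masks: Dict[str, np.ndarray] = field(default_factory=dict)
    image_size: Optional[tuple] = None  # (height, width)


@dataclass
class SubmissionFrame:
    """Predicted boxes (with confidences) and per-class masks for one frame."""

    frame_id: str
    boxes: List[Box] = field(default_factory=list)
    masks: Dict[str, np.ndarray] = field(default_factory=dict)


def _parse_box_line(line: str, lineno: int, catalog: ClassCatalog, with_confidence: bool) -> Box:
    parts = line.split()
    n_expected = 6 if with_confidence else 5
    if len(parts) != n_expected:
        raise FormatError(f"line {lineno}: expected {n_expected} fields, got {len(parts)}: {line!r}")
    name = parts[0]
    if name not in catalog.detection_classes:
        raise FormatError(f"line {lineno}: unknown class name {name!r}")
    try:
        nums = [float(v) for v in parts[1:]]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-numeric field in {line!r}") from exc
    if with_confidence:
        conf, x1, y1, x2, y2 = nums
        if not (0.0 <= conf <= 1.0):
            raise FormatError(f"line {lineno}: confidence {conf} outside [0, 1]")
    else:
        conf = None
        x1, y1, x2, y2 = nums
    if x2 <= x1 or y2 <= y1:
        raise FormatError(f"line {lineno}: degenerate box ({x1}, {y1}, {x2}, {y2})")
    return Box(class_label=name, x1=x1, y1=y1, x2=x2, y2=y2, confidence=conf)


def read_detection_file(path, catalog: ClassCatalog = EAD_CATALOG) -> SubmissionFrame:
    """Parse a prediction text file into a :class:`SubmissionFrame`.

    Boxes come back in reading order; an empty file yields zero boxes.
    """
    path = Path(path)
    frame = SubmissionFrame(frame_id=path.stem)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        frame.boxes.append(_parse_box_line(line, lineno, catalog, with_confidence=True))
    return frame


def write_detection_file(path, frame: SubmissionFrame) -> None:
    lines = [
        f"{b.class_label} {b.confidence:g} {b.x1:g} {b.y1:g} {b.x2:g} {b.y2:g}"
        for b in frame.boxes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gt_box_file(path, catalog: ClassCatalog = EAD_CATALOG) -> FrameAnnotations:
    """Parse a ground-truth box file (no confidence column)."""
    path = Path(path)
    ann = FrameAnnotations(frame_id=path.stem)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        ann.boxes.append(_parse_box_line(line, lineno, catalog, with_confidence=False))
    return ann


def write_gt_box_file(path, ann: FrameAnnotations) -> None:
    lines = [f"{b.class_label} {b.x1:g} {b.y1:g} {b.x2:g} {b.y2:g}" for b in ann.boxes]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_mask_set(directory, frame_id: str, catalog: ClassCatalog = EAD_CATALOG) -> Dict[str, np.ndarray]:
    """Load the per-class binary masks ``<frame_id>_<class>.png`` for a frame.

    The result always contains exactly the catalog's segmentation classes; a
    missing class file becomes an all-zero mask of the common shape (logged).
    Pixel values are coerced to {0, 1} (any value > 0 is foreground).
    """
    directory = Path(directory)
    masks: Dict[str, np.ndarray] = {}
    shape = None
    for cls in catalog.segmentation_classes:
        p = directory / f"{frame_id}_{cls}.png"
        if not p.exists():
            continue
        arr = np.asarray(Image.open(p).convert("L"))
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(
                f"mask shape mismatch for frame {frame_id}: {arr.shape} vs {shape}"
            )
        masks[cls] = (arr > 0).astype(np.uint8)
    if shape is None:
        raise FormatError(f"no mask files found for frame {frame_id} in {directory}")
    for cls in catalog.segmentation_classes:
        if cls not in masks:
            logger.warning("frame %s: missing mask for class %r, scored all-zero", frame_id, cls)
            masks[cls] = np.zeros(shape, dtype=np.uint8)
    return masks


def write_mask_set(directory, frame_id: str, masks: Mapping[str, np.ndarray]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cls, mask in masks.items():
        img = Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255)
        img.save(directory / f"{frame_id}_{cls}.png")


def read_submission_dir(directory, catalog: ClassCatalog = EAD_CATALOG, with_masks: bool = False,
                        mask_shape: Optional[tuple] = None) -> Dict[str, SubmissionFrame]:
    """Read every ``*.txt`` prediction file (and optionally masks) in a directory."""
    directory = Path(directory)
    frames: Dict[str, SubmissionFrame] = {}
    for p in sorted(directory.glob("*.txt")):
        frame = read_detection_file(p, catalog)
        if with_masks:
            try:
                frame.masks = read_mask_set(directory, frame.frame_id, catalog)
            except FormatError:
                if mask_shape is not None:
                    frame.masks = {
                        cls: np.zeros(mask_shape, dtype=np.uint8)
                        for cls in catalog.segmentation_classes
                    }
        frames[frame.frame_id] = frame
    return frames


def read_gt_dir(directory, catalog: ClassCatalog = EAD_CATALOG, with_masks: bool = False) -> Dict[str, FrameAnnotations]:
    directory = Path(directory)
    frames: Dict[str, FrameAnnotations] = {}
    for p in sorted(directory.glob("*.txt")):
        ann = read_gt_box_file(p, catalog)
        if with_masks:
            ann.masks = read_mask_set(directory, ann.frame_id, catalog)
            ann.image_size = next(iter(ann.masks.values())).shape
        frames[ann.frame_id] = ann
    return frames


def validate_submission(sub: Mapping[str, SubmissionFrame],
                        gt: Mapping[str, FrameAnnotations]) -> dict:
    """Report-only alignment check between a submission and the ground truth.

    Frames missing from the submission are scored as empty predictions;
    extra frames are ignored with a warning.
    """
    missing = sorted(set(gt) - set(sub))
    extra = sorted(set(sub) - set(gt))
    for fid in missing:
        logger.warning("frame %s missing from submission: scored as empty prediction", fid)
    for fid in extra:
        logger.warning("frame %s not in ground truth: ignored", fid)
    return {"missing_scored_empty": missing, "ignored_extra": extra}


def load_config(path) -> dict:
    """Load the YAML evaluation config (class catalog, thresholds, weights, seed)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "classes" in cfg:
        det = tuple(cfg["classes"].get("detection", EAD_CATALOG.detection_classes))
        seg = tuple(cfg["classes"].get("segmentation", EAD_CATALOG.segmentation_classes))
        cfg["catalog"] = ClassCatalog(det, seg)
    else:
        cfg["catalog"] = EAD_CATALOG
    cfg.setdefault("iou_thresh", 0.25)
    cfg.setdefault("min_fraction", 0.5)
    cfg.setdefault("seed", 0)
    return cfg
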