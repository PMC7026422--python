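"""Synthetic ground-truth / prediction fixtures and embedded leaderboards.

The generator emulates the statistical shape of endoscopy artefact
annotations rather than their appearance: seven classes with very different
per-frame frequencies and box-size distributions, where the hard classes
(miscellaneous artefacts, bubbles) are small in area and frequently placed
*inside* boxes of larger classes, and the same location may carry several
class labels.  Masks for the five segmentation classes are rasterised from
the boxes (filled rectangles), which is sufficient for exercising pixel
metrics but is not photorealistic.

``perturb_to_predictions`` degrades a ground truth in controlled ways —
localisation jitter, dropped boxes, label swaps, spurious detections — with
confidences produced by a monotone map of each surviving box's IoU with its
source, so that ranking by confidence carries real signal.  All randomness
flows from the seed in the spec; identical specs give identical fixtures.

``leaderboard_fixture`` returns the published per-team metric tables of the
challenge (detection/generalization, class-specific detection, and
segmentation) as versioned DataFrames for rank analyses and identity tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry_metrics import Box, rasterize_box
from .io_formats import EAD_CATALOG, ClassCatalog, FrameAnnotations, SubmissionFrame

__all__ = ["FixtureSpec", "PerturbationSpec", "generate_ground_truth",
           "perturb_to_predictions", "leaderboard_fixture"]

#: Expected boxes per frame per class.  Specularity dominates; the two hard
#: classes (artefact, bubbles) are common; blur/contrast/instrument are rarer
#: frame-level phenomena.
_DEFAULT_FREQS = {
    "specularity": 3.0,
    "saturation": 1.0,
    "artefact": 2.0,
    "blur": 0.5,
    "contrast": 0.5,
    "bubbles": 2.0,
    "instrument": 0.5,
}

#: (mean, sd) of box area as a fraction of frame area.  artefact and bubbles
#: are deliberately small — the structure behind their poor leaderboard
#: scores — while blur/contrast/saturation cover large regions.
_DEFAULT_SIZES = {
    "specularity": (0.004, 0.003),
    "saturation": (0.06, 0.03),
    "artefact": (0.003, 0.002),
    "blur": (0.15, 0.06),
    "contrast": (0.12, 0.05),
    "bubbles": (0.004, 0.003),
    "instrument": (0.05, 0.02),
}

_SMALL_CLASSES = ("specularity", "artefact", "bubbles")
_LARGE_CLASSES = ("saturation", "blur", "contrast", "instrument")


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth generator settings; identical specs are bit-reproducible."""

    n_frames: int = 50
    image_size: Tuple[int, int] = (256, 256)  # (height, width) px
    class_freqs: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_FREQS))
    size_dist: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_SIZES))
    overlap_rate: float = 0.6
    seed: int = 0
    catalog: ClassCatalog = EAD_CATALOG


def _conf_from_iou(iou: float) -> float:
    """Default monotone IoU -> confidence map for perturbed predictions."""
    return 0.2 + 0.75 * iou


@dataclass(frozen=True)
class PerturbationSpec:
    """Controlled degradation of a ground truth into a prediction set."""

    loc_noise_sd: float = 0.0      # px jitter on each box edge
    drop_prob: float = 0.0
    mislabel_prob: float = 0.0
    spurious_rate: float = 0.0     # spurious boxes per frame (Poisson mean)
    conf_model: Callable[[float], float] = _conf_from_iou
    seed: int = 0


def _sample_box(rng: np.random.Generator, cls: str, spec: FixtureSpec,
                inside: Optional[Box] = None) -> Box:
    h, w = spec.image_size
    mean_a, sd_a = spec.size_dist[cls]
    area_frac = float(np.clip(rng.normal(mean_a, sd_a), 1e-4, 0.8))
    aspect = float(np.exp(rng.normal(0.0, 0.3)))
    bw = np.sqrt(area_frac * h * w * aspect)
    bh = np.sqrt(area_frac * h * w / aspect)
    bw = float(np.clip(bw, 2.0, w - 1))
    bh = float(np.clip(bh, 2.0, h - 1))
    if inside is not None:
        # center the small box uniformly inside the host box
        cx = rng.uniform(inside.x1, inside.x2)
        cy = rng.uniform(inside.y1, inside.y2)
    else:
        cx = rng.uniform(bw / 2, w - bw / 2)
        cy = rng.uniform(bh / 2, h - bh / 2)
    x1 = float(np.clip(cx - bw / 2, 0, w - 2))
    y1 = float(np.clip(cy - bh / 2, 0, h - 2))
    x2 = float(np.clip(cx + bw / 2, x1 + 1, w))
    y2 = float(np.clip(cy + bh / 2, y1 + 1, h))
    return Box(class_label=cls, x1=x1, y1=y1, x2=x2, y2=y2)


def _masks_from_boxes(boxes, catalog: ClassCatalog, image_size) -> Dict[str, np.ndarray]:
    h, w = image_size
    masks = {cls: np.zeros((h, w), dtype=np.uint8) for cls in catalog.segmentation_classes}
    for b in boxes:
        if b.class_label in masks:
            masks[b.class_label] |= rasterize_box(b, h, w)
    return masks


def generate_ground_truth(spec: FixtureSpec = FixtureSpec(),
                          with_masks: bool = True) -> Dict[str, FrameAnnotations]:
    """Sample a reproducible set of annotated frames from a fixture spec.

    Large-class boxes are placed first; each small-class box is then placed
    inside a uniformly chosen large box with probability ``overlap_rate``,
    reproducing the heavy colocalisation of small artefact classes.
    """
    rng = np.random.default_rng(spec.seed)
    frames: Dict[str, FrameAnnotations] = {}
    for fi in range(spec.n_frames):
        fid = f"frame_{fi:05d}"
        boxes = []
        hosts = []
        for cls in _LARGE_CLASSES:
            if cls not in spec.class_freqs:
                continue
            for _ in range(rng.poisson(spec.class_freqs[cls])):
                b = _sample_box(rng, cls, spec)
                boxes.append(b)
                hosts.append(b)
        for cls in _SMALL_CLASSES:
            if cls not in spec.class_freqs:
                continue
            for _ in range(rng.poisson(spec.class_freqs[cls])):
                inside = None
                if hosts and rng.random() < spec.overlap_rate:
                    inside = hosts[rng.integers(len(hosts))]
                boxes.append(_sample_box(rng, cls, spec, inside=inside))
        ann = FrameAnnotations(frame_id=fid, boxes=boxes, image_size=spec.image_size)
        if with_masks:
            ann.masks = _masks_from_boxes(boxes, spec.catalog, spec.image_size)
        frames[fid] = ann
    return frames


def perturb_to_predictions(gt: Mapping[str, FrameAnnotations],
                           pspec: PerturbationSpec = PerturbationSpec(),
                           catalog: ClassCatalog = EAD_CATALOG,
                           with_masks: bool = False) -> Dict[str, SubmissionFrame]:
    """Degrade a ground truth into a seeded synthetic submission.

    With all noise parameters at zero the output is geometrically identical
    to the ground truth (confidences from ``conf_model(1.0)``), so a perfect
    submission is always constructible.
    """
    rng = np.random.default_rng(pspec.seed)
    subs: Dict[str, SubmissionFrame] = {}
    classes = list(catalog.detection_classes)
    for fid in sorted(gt):
        ann = gt[fid]
        h, w = ann.image_size if ann.image_size else (256, 256)
        preds = []
        for b in ann.boxes:
            if rng.random() < pspec.drop_prob:
                continue
            if pspec.loc_noise_sd > 0:
                dx1, dy1, dx2, dy2 = rng.normal(0.0, pspec.loc_noise_sd, size=4)
            else:
                dx1 = dy1 = dx2 = dy2 = 0.0
            x1 = float(np.clip(b.x1 + dx1, 0, w - 2))
            y1 = float(np.clip(b.y1 + dy1, 0, h - 2))
            x2 = float(np.clip(b.x2 + dx2, x1 + 1, w))
            y2 = float(np.clip(b.y2 + dy2, y1 + 1, h))
            cls = b.class_label
            if pspec.mislabel_prob > 0 and rng.random() < pspec.mislabel_prob:
                others = [c for c in classes if c != cls]
                cls = others[rng.integers(len(others))]
            from .geometry_metrics import box_iou
            jittered = Box(class_label=cls, x1=x1, y1=y1, x2=x2, y2=y2)
            iou = box_iou(Box(class_label=cls, x1=b.x1, y1=b.y1, x2=b.x2, y2=b.y2), jittered)
            conf = float(np.clip(pspec.conf_model(iou), 0.0, 1.0))
            preds.append(replace(jittered, confidence=conf))
        for _ in range(rng.poisson(pspec.spurious_rate)):
            cls = classes[rng.integers(len(classes))]
            bw = rng.uniform(4, w / 4)
            bh = rng.uniform(4, h / 4)
            x1 = rng.uniform(0, w - bw)
            y1 = rng.uniform(0, h - bh)
            conf = float(np.clip(pspec.conf_model(0.0) * rng.uniform(0.2, 1.0), 0.0, 1.0))
            preds.append(Box(class_label=cls, x1=float(x1), y1=float(y1),
                             x2=float(x1 + bw), y2=float(y1 + bh), confidence=conf))
        frame = SubmissionFrame(frame_id=fid, boxes=preds)
        if with_masks:
            frame.masks = _masks_from_boxes(preds, catalog, (h, w))
        subs[fid] = frame
    return subs


# ---------------------------------------------------------------------------
# Published leaderboard tables (versioned data fixtures, values as printed).
# ---------------------------------------------------------------------------

_TABLE2_COLUMNS = ["mAP_d", "IoU_d", "score_d", "mAP_g", "IoU_g", "dev_g"]
_TABLE2_ROWS = {
    "yangsuhui":               [0.3235, 0.4172, 0.3610, 0.3187, 0.0734, 0.1018],
    "ZhangPY":                 [0.3117, 0.4051, 0.3491, 0.3518, 0.0889, 0.0984],
    "Keisecker":               [0.3087, 0.3997, 0.3451, 0.2848, 0.3902, 0.0696],
    "VegZhang":                [0.3371, 0.3517, 0.3429, 0.3991, 0.1783, 0.1010],
    "YWa":                     [0.3842, 0.2368, 0.3252, 0.3746, 0.1481, 0.0424],
    "michaelqiyao":            [0.3842, 0.2368, 0.3252, 0.3746, 0.1780, 0.0742],
    "ilkayoksuz":              [0.2719, 0.3456, 0.3014, 0.2974, 0.0688, 0.0859],
    "swtnb":                   [0.2901, 0.3180, 0.3013, 0.2914, 0.2547, 0.0854],
    "Witt":                    [0.3148, 0.2621, 0.2937, 0.2897, 0.1854, 0.1003],
    "akhanss":                 [0.2581, 0.3330, 0.2880, 0.2187, 0.2262, 0.0770],
    "XiaokangWang":            [0.2621, 0.3205, 0.2855, 0.2515, 0.2058, 0.0728],
    "a545306097":              [0.2547, 0.2719, 0.2616, 0.1122, 0.2244, 0.1298],
    "nqt52798669":             [0.3068, 0.1222, 0.2330, 0.3154, 0.0871, 0.0515],
    "ShufanYang":              [0.2208, 0.1955, 0.2107, 0.1931, 0.1365, 0.0478],
    "xiaohong1":               [0.2416, 0.3482, 0.2842, 0.1764, 0.2671, 0.0555],
    "Faster R-CNN (baseline)": [0.2226, 0.2751, 0.2436, 0.2172, 0.1647, 0.0893],
    "Retinanet (baseline)":    [0.2135, 0.2270, 0.2189, 0.2499, 0.1679, 0.0665],
    "Merged (super baseline)": [0.3331, 0.3793, 0.3516, 0.3433, 0.2610, 0.0610],
}

# class-specific (mAP, IoU) pairs for the top-30% teams and baselines;
# class order: blur, contrast, specularity, saturation, artefact, bubbles,
# instrument.
_TABLE3_CLASSES = ["blur", "contrast", "specularity", "saturation",
                   "artefact", "bubbles", "instrument"]
_TABLE3_ROWS = {
    "yangsuhui":    [0.28, 0.45, 0.44, 0.29, 0.48, 0.30, 0.48, 0.33, 0.32, 0.32, 0.06, 0.77, 0.26, 0.46],
    "ZhangPY":      [0.33, 0.41, 0.41, 0.41, 0.35, 0.34, 0.45, 0.38, 0.20, 0.40, 0.20, 0.27, 0.24, 0.62],
    "Keisecker":    [0.31, 0.50, 0.40, 0.38, 0.36, 0.29, 0.38, 0.43, 0.23, 0.37, 0.18, 0.26, 0.30, 0.56],
    "michaelqiyao": [0.37, 0.22, 0.47, 0.25, 0.48, 0.22, 0.52, 0.29, 0.31, 0.26, 0.24, 0.08, 0.30, 0.33],
    "ilkayoksuz":   [0.25, 0.33, 0.32, 0.34, 0.27, 0.30, 0.35, 0.36, 0.24, 0.38, 0.19, 0.25, 0.29, 0.45],
    "swtnb":        [0.34, 0.23, 0.44, 0.21, 0.28, 0.27, 0.32, 0.36, 0.23, 0.33, 0.17, 0.30, 0.25, 0.52],
    "Faster R-CNN": [0.17, 0.35, 0.33, 0.21, 0.21, 0.37, 0.33, 0.15, 0.15, 0.19, 0.11, 0.10, 0.21, 0.45],
    "Retinanet":    [0.21, 0.20, 0.32, 0.25, 0.12, 0.17, 0.39, 0.32, 0.12, 0.24, 0.18, 0.15, 0.16, 0.27],
    "Merged":       [0.32, 0.37, 0.45, 0.37, 0.37, 0.31, 0.43, 0.41, 0.26, 0.39, 0.23, 0.30, 0.27, 0.51],
}

_TABLE4_COLUMNS = ["DSC", "Jaccard", "Overlap", "F2", "PPV", "Recall", "s_score"]
_TABLE4_ROWS = {
    "yangsuhui":               [0.6810, 0.6416, 0.6612, 0.6779, 0.8789, 0.7148, 0.6654],
    "swtnb":                   [0.6496, 0.6041, 0.6269, 0.6585, 0.7515, 0.7594, 0.6348],
    "YWa":                     [0.6392, 0.6021, 0.6206, 0.6243, 0.9039, 0.6602, 0.6216],
    "VegZhang":                [0.6141, 0.5831, 0.6185, 0.6185, 0.8386, 0.6839, 0.6036],
    "michaelqiyao":            [0.6141, 0.5787, 0.5964, 0.6171, 0.8164, 0.6987, 0.6016],
    "Ig920810":                [0.6079, 0.5684, 0.5882, 0.5972, 0.8189, 0.6802, 0.5904],
    "Weiminson":               [0.6011, 0.5631, 0.5821, 0.5839, 0.8375, 0.6598, 0.5825],
    "ZhangPY":                 [0.5719, 0.5397, 0.5558, 0.5701, 0.7719, 0.6581, 0.5594],
    "nqt52798669":             [0.5414, 0.4998, 0.5060, 0.5331, 0.6290, 0.6887, 0.5237],
    "ShuganYang":              [0.4119, 0.3797, 0.3958, 0.3998, 0.6407, 0.6360, 0.3968],
    "U-Net (baseline)":        [0.5490, 0.5030, 0.5260, 0.5580, 0.6691, 0.7488, 0.5340],
    "Merged (super baseline)": [0.6782, 0.6356, 0.6569, 0.6703, 0.8747, 0.7178, 0.6603],
}


def leaderboard_fixture(table_id: str) -> pd.DataFrame:
    """Return a published leaderboard table as a teams x metrics DataFrame.

    ``"table2"``: detection + generalization scores per team.
    ``"table3"``: class-specific mAP/IoU (columns ``mAP_<class>``,
    ``IoU_<class>``) for the top-30% teams and baselines.
    ``"table4"``: segmentation metrics per team.
    """
    if table_id == "table2":
        return pd.DataFrame.from_dict(_TABLE2_ROWS, orient="index",
                                      columns=_TABLE2_COLUMNS)
    if table_id == "table3":
        cols = []
        for cls in _TABLE3_CLASSES:
            cols += [f"mAP_{cls}", f"IoU_{cls}"]
        return pd.DataFrame.from_dict(_TABLE3_ROWS, orient="index", columns=cols)
    if table_id == "table4":
        return pd.DataFrame.from_dict(_TABLE4_ROWS, orient="index",
                                      columns=_TABLE4_COLUMNS)
    raise ValueError(f"unknown leaderboard table {table_id!r}")
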