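"""Out-of-sample generalization scoring.

A robust detector should perform about equally on its test set and on data
from an institution it never saw.  Per class i the deviation between the
two mean-average-precision values is gated by a relative tolerance:

    dev_g^i = 0                       if |mAP_d^i - mAP_g^i| / mAP_d^i <= 0.1
    dev_g^i = |mAP_d^i - mAP_g^i|     otherwise

and dev_g is the unweighted mean of dev_g^i over the N detection classes.
Fluctuations within 10% of the in-domain class mAP are treated as noise;
larger drifts are penalised by their full magnitude.

Teams are ordered by the rank-combined score

    score_g = 1/3 * Rank(dev_g) + 2/3 * Rank(mAP_g)

with ties given average ranks; lower score_g is better.  By default
Rank(mAP_g) puts rank 1 on the *highest* mAP_g so that a low score_g always
means a good generaliser; the literal ascending ordering is available via
``ascending_map_g=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .detection_eval import DetectionScorecard

logger = logging.getLogger(__name__)

__all__ = ["GeneralizationReport", "class_deviation", "generalization_deviation",
           "generalization_rank_score"]


@dataclass
class GeneralizationReport:
    per_class_dev: Dict[str, float]
    dev_g: float
    mAP_d: float
    mAP_g: float


def class_deviation(map_d: float, map_g: float, tol: float = 0.1) -> float:
    """Tolerance-gated absolute mAP deviation for one class.

    The tolerance boundary is inclusive: a relative deviation of exactly
    ``tol`` still counts as stable (deviation 0).  ``map_d = 0`` cannot be
    divided by; we define the deviation as ``map_g`` in that case (0 when
    both are 0), and log the extension.
    """
    if not (0.0 <= map_d <= 1.0 and 0.0 <= map_g <= 1.0):
        raise ValueError("mAP values must lie in [0, 1]")
    if map_d == 0.0:
        if map_g > 0.0:
            logger.info("class with mAP_d = 0 and mAP_g = %g: deviation set to mAP_g", map_g)
        return map_g
    diff = abs(map_d - map_g)
    if diff / map_d <= tol:
        return 0.0
    return diff


def generalization_deviation(card_d: DetectionScorecard,
                             card_g: DetectionScorecard,
                             tol: float = 0.1) -> GeneralizationReport:
    """Mean tolerance-gated deviation between in-domain and out-of-sample scorecards.

    Classes without reference boxes in either scorecard (AP ``None``) are
    excluded; N is the number of classes compared.
    """
    if set(card_d.per_class_ap) != set(card_g.per_class_ap):
        raise ValueError("scorecards cover different class sets")
    per_class: Dict[str, float] = {}
    for cls in card_d.per_class_ap:
        ad, ag = card_d.per_class_ap[cls], card_g.per_class_ap[cls]
        if ad is None or ag is None:
            continue
        per_class[cls] = class_deviation(ad, ag, tol)
    if not per_class:
        raise ValueError("no class is scored in both scorecards")
    return GeneralizationReport(per_class_dev=per_class,
                                dev_g=float(np.mean(list(per_class.values()))),
                                mAP_d=card_d.mAP, mAP_g=card_g.mAP)


def generalization_rank_score(teams: Mapping[str, Tuple[float, float]],
                              ascending_map_g: bool = False) -> Dict[str, float]:
    """score_g = 1/3·Rank(dev_g) + 2/3·Rank(mAP_g) per team; lower is better.

    ``teams`` maps a team name to ``(dev_g, mAP_g)``.  Rank(dev_g) is
    ascending (rank 1 = smallest deviation); Rank(mAP_g) is descending by
    default (rank 1 = highest mAP_g).  Ties get average ranks.
    """
    if len(teams) < 2:
        raise ValueError("need at least two teams to rank")
    names = list(teams)
    dev = np.array([teams[t][0] for t in names], dtype=float)
    mag = np.array([teams[t][1] for t in names], dtype=float)
    r_dev = rankdata(dev, method="average")
    r_map = rankdata(mag if ascending_map_g else -mag, method="average")
    score = r_dev / 3.0 + 2.0 * r_map / 3.0
    return {t: float(s) for t, s in zip(names, score)}
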