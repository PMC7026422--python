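"""Nonparametric rank statistics and the clinical-applicability ranking.

Methods are compared across artefact classes (the blocks) with the Friedman
test; post-hoc pairwise structure comes from the Nemenyi critical difference
or, against a fixed control, from Bonferroni-Dunn z-tests.  The
Jonckheere-Terpstra test checks for a monotone trend of scores across
class groups placed in a meaningful order (e.g. by annotation count or mean
artefact size); its p-value is computed by seeded permutation because the
group sizes here are small.

Clinical applicability weighs accuracy, consistency of per-class
performance and computational efficiency ranks at 0.4 / 0.5 / 0.1.
Consistency of a method is the standard deviation of its per-class scores
divided by their mean, so it is scale-free and low for class-stable
methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalWeights",
    "friedman_test",
    "nemenyi_critical_difference",
    "nemenyi_posthoc",
    "bonferroni_dunn_posthoc",
    "jonckheere_terpstra",
    "consistency_ratio",
    "clinical_rank",
    "impute_missing_ranks",
]


@dataclass(frozen=True)
class ClinicalWeights:
    accuracy: float = 0.4
    consistency: float = 0.5
    efficiency: float = 0.1

    def __post_init__(self) -> None:
        if abs(self.accuracy + self.consistency + self.efficiency - 1.0) > 1e-12:
            raise ValueError("clinical weights must sum to 1")


def friedman_test(scores: np.ndarray) -> Tuple[float, float, np.ndarray]:
    """Friedman chi-square test on a methods x blocks score grid.

    Ranks are assigned within each block (column) across methods, with ties
    averaged; higher score = higher rank number.  Returns the tie-corrected
    chi-square statistic, its p-value (chi-square approximation, k-1 df) and
    the per-method mean ranks.  A grid where every block is fully tied has
    no rank information: statistic 0, p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D methods x blocks grid")
    k, n = scores.shape
    if k < 3 or n < 2:
        raise ValueError(f"need >= 3 methods and >= 2 blocks, got {k} x {n}")
    ranks = np.apply_along_axis(stats.rankdata, 0, scores)
    mean_ranks = ranks.mean(axis=1)
    ssbn = float(np.sum(ranks.sum(axis=1) ** 2))
    ties = 0.0
    for j in range(n):
        _, counts = np.unique(scores[:, j], return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (k * (k * k - 1) * n)
    if c == 0.0:  # every block fully tied
        return 0.0, 1.0, mean_ranks
    statistic = (12.0 / (k * n * (k + 1)) * ssbn - 3.0 * n * (k + 1)) / c
    statistic = max(statistic, 0.0)
    pvalue = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), pvalue, mean_ranks


def nemenyi_critical_difference(k: int, n: int, alpha: float = 0.05) -> float:
    """CD = q_alpha * sqrt(k(k+1) / (6n)), q from the studentized range (df=inf)."""
    q_alpha = stats.studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * n)))


def nemenyi_posthoc(mean_ranks: Sequence[float], n: int,
                    alpha: float = 0.05) -> Tuple[np.ndarray, float]:
    """Pairwise significance grid from the Nemenyi critical difference.

    Entry (i, j) is True when |mean_rank_i - mean_rank_j| >= CD.  ``n`` is
    the number of blocks the mean ranks were averaged over.
    """
    mean_ranks = np.asarray(mean_ranks, dtype=float)
    k = len(mean_ranks)
    cd = nemenyi_critical_difference(k, n, alpha)
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    sig = diff >= cd
    np.fill_diagonal(sig, False)
    return sig, cd


def bonferroni_dunn_posthoc(mean_ranks: Mapping[str, float], control: str,
                            n: int, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn z-tests of every method against a control, Bonferroni-corrected.

    z_i = (R_i - R_control) / sqrt(k(k+1)/(6n)); a method differs
    significantly from the control when its two-sided p < alpha / (k - 1).
    """
    if control not in mean_ranks:
        raise ValueError(f"control {control!r} not among methods")
    k = len(mean_ranks)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    rows = []
    rc = mean_ranks[control]
    for name, r in mean_ranks.items():
        z = (r - rc) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"method": name, "z": z, "p": p,
                     "significant": bool(name != control and p < alpha / (k - 1))})
    return pd.DataFrame(rows).set_index("method")


def _jt_statistic(groups: Sequence[np.ndarray]) -> float:
    j = 0.0
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            x, y = groups[a], groups[b]
            gt = np.sum(y[None, :] > x[:, None])
            eq = np.sum(y[None, :] == x[:, None])
            j += float(gt) + 0.5 * float(eq)
    return j


def jonckheere_terpstra(groups: Sequence[Sequence[float]], n_perm: int = 10_000,
                        seed: Optional[int] = None,
                        method: str = "permutation") -> Tuple[float, float]:
    """One-sided test for an increasing trend across ordered groups.

    The statistic J counts, over every earlier-group/later-group pair of
    observations, how often the later value exceeds the earlier (ties count
    half).  The p-value is P(J_perm >= J_obs) over ``n_perm`` seeded random
    relabellings of group membership (``method="permutation"``), or from
    the asymptotic normal approximation (``method="normal"``).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 ordered, nonempty groups")
    j_obs = _jt_statistic(groups)
    sizes = [len(g) for g in groups]
    if method == "normal":
        n_tot = sum(sizes)
        sq = sum(s * s for s in sizes)
        mean = (n_tot * n_tot - sq) / 4.0
        var = (n_tot**2 * (2 * n_tot + 3) - sum(s * s * (2 * s + 3) for s in sizes)) / 72.0
        z = (j_obs - mean) / np.sqrt(var)
        return j_obs, float(stats.norm.sf(z))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 100:
        import warnings
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(groups)
    edges = np.cumsum(sizes)[:-1]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _jt_statistic(np.split(perm, edges)) >= j_obs - 1e-12:
            count += 1
    return j_obs, (count + 1) / (n_perm + 1)


def consistency_ratio(values: Sequence[float]) -> float:
    """Sample standard deviation of per-class scores divided by their mean.

    Scale-invariant; 0 for perfectly class-stable methods.  Undefined
    (NaN) when the mean is not positive.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean <= 0:
        return float("nan")
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / mean)


def impute_missing_ranks(ranks: Mapping[str, Optional[float]]) -> Dict[str, float]:
    """Replace missing (None/NaN) ranks with the worst observed rank + 1."""
    observed = [r for r in ranks.values() if r is not None and np.isfinite(r)]
    worst = (max(observed) + 1) if observed else 1.0
    return {t: (r if r is not None and np.isfinite(r) else worst)
            for t, r in ranks.items()}


def clinical_rank(acc_ranks: Mapping[str, float], cons_ranks: Mapping[str, float],
                  eff_ranks: Mapping[str, Optional[float]],
                  weights: ClinicalWeights = ClinicalWeights()) -> pd.DataFrame:
    """Weighted clinical-applicability ranking from three sub-rank vectors.

    weighted = 0.4·accuracy + 0.5·consistency + 0.1·efficiency (defaults);
    the final rank orders teams by ascending weighted value, ties averaged.
    Missing efficiency ranks are imputed with the worst observed rank + 1.
    """
    teams = set(acc_ranks)
    if set(cons_ranks) != teams or set(eff_ranks) != teams:
        raise ValueError("accuracy, consistency and efficiency rank the same team set")
    eff = impute_missing_ranks(eff_ranks)
    names = sorted(teams)
    weighted = np.array([
        weights.accuracy * acc_ranks[t] + weights.consistency * cons_ranks[t]
        + weights.efficiency * eff[t] for t in names
    ])
    final = stats.rankdata(weighted, method="average")
    return pd.DataFrame({"weighted": weighted, "clinical_rank": final}, index=names)
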