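"""Gwet's AC1 chance-corrected inter-rater agreement.

AC1 corrects observed agreement by the chance that two raters agree "by
accident", estimated from the mean marginal prevalence of each category;
unlike Cohen's kappa it stays well behaved when one category dominates
(as grey vs not-grey pixel masks do).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import UndefinedCoefficientError


@dataclass
class AgreementResult:
    ac1: float
    pa: float  # observed agreement
    pe: float  # chance agreement
    n_items: int
    n_categories: int


def gwet_ac1(labels_a, labels_b, categories=None) -> AgreementResult:
    """AC1 = (Pa - Pe) / (1 - Pe) for two raters.

    Pa is the fraction of identically labelled items; Pe is Gwet's chance
    term (1/(K-1)) sum_k q_k (1 - q_k) with q_k the mean of the two raters'
    marginal proportions for category k. ``categories`` fixes the label
    universe (K); by default it is the union of observed labels.
    """
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size == 0 or a.size != b.size:
        raise ValueError("label vectors must be nonempty and equal length")
    cats = np.unique(np.concatenate([a, b])) if categories is None else np.asarray(categories)
    k = len(cats)
    if k < 2:
        raise ValueError("need at least 2 categories in the label universe")

    pa = float(np.mean(a == b))
    q = np.array([(np.mean(a == c) + np.mean(b == c)) / 2.0 for c in cats])
    pe = float(np.sum(q * (1.0 - q)) / (k - 1))
    if pe >= 1.0:
        raise UndefinedCoefficientError("chance agreement is 1; AC1 undefined")
    return AgreementResult(float((pa - pe) / (1.0 - pe)), pa, pe, int(a.size), k)


def pairwise_ac1(masks: list[np.ndarray], names: list[str] | None = None) -> dict:
    """All pairwise AC1 values over >= 2 rater masks, plus their mean.

    Masks are compared pixel-wise over their common shape with categories
    {grey, not-grey}. Returns {"pairs": [...], "mean_ac1": float}.
    """
    if len(masks) < 2:
        raise ValueError("need at least two rater masks")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("rater masks must share a shape")
    names = names or [f"rater{i+1}" for i in range(len(masks))]
    pairs = []
    for i, j in combinations(range(len(masks)), 2):
        res = gwet_ac1(
            np.asarray(masks[i], bool), np.asarray(masks[j], bool), categories=[False, True]
        )
        pairs.append(
            {
                "raters": (names[i], names[j]),
                "ac1": res.ac1,
                "pa": res.pa,
                "pe": res.pe,
            }
        )
    return {"pairs": pairs, "mean_ac1": float(np.mean([p["ac1"] for p in pairs]))}
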