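"""Segmentation-quality metrics and inter-observer agreement.

Confusion-count scores (Dice/DSC, Matthews correlation, F_beta, true
positive ratio) are computed one-vs-rest per branch class and for the
whole-bifurcation foreground union.  Degenerate denominators follow
documented conventions (see the individual functions).  Fleiss kappa
summarizes agreement among a fixed number of raters assigning ordinal
quality scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .io_core import CODE_TABLE, LabelMap, same_grid


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest voxel counts for a single class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Voxelwise confusion counts between two binary masks of equal shape."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def dice(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN).

    Convention: empty truth and empty prediction -> 1.0 (perfect agreement
    on absence); empty truth with non-empty prediction -> 0.0.
    """
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2.0 * c.tp / denom


def tpr(c: ConfusionCounts) -> float:
    """True positive ratio (sensitivity/recall) TP/(TP+FN); empty truth -> 1.0
    when the prediction is also empty, else 0.0."""
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when any marginal is empty
    (the correlation is undefined there and 0 is the uninformative value)."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return float(num / np.sqrt(float(denom)))


def f_beta_score(c: ConfusionCounts, beta: float,
                 variant: str = "precision_recall") -> float:
    """F_beta on confusion counts.

    The default combines precision and recall,
    ``F_beta = (1+b^2) P R / (b^2 P + R)``, which for beta=1 is identical
    to Dice.  ``variant='specificity_sensitivity'`` evaluates the same
    functional form on (specificity, sensitivity) instead — a literal
    alternative reading that is near-degenerate on class-imbalanced
    volumes (specificity saturates at 1) and is provided for completeness,
    not as the default.  Empty-truth conventions follow :func:`dice`.
    """
    b2 = beta * beta
    if variant == "precision_recall":
        denom = (1 + b2) * c.tp + b2 * c.fn + c.fp
        if denom == 0:
            return 1.0 if c.fp == 0 else 0.0
        return (1 + b2) * c.tp / denom
    if variant == "specificity_sensitivity":
        spec = 1.0 if c.tn + c.fp == 0 else c.tn / (c.tn + c.fp)
        sens = tpr(c)
        denom = b2 * spec + sens
        return 0.0 if denom == 0 else (1 + b2) * spec * sens / denom
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class MetricsReport:
    """Per-class and whole-bifurcation scores.

    ``per_class`` maps class name (CCA/ICA/ECA) to a dict of scores
    {dsc, mcc, f2, f05, tpr}; ``whole`` holds the same scores for the
    foreground union.
    """

    per_class: dict[str, dict[str, float]]
    whole: dict[str, float]

    def as_rows(self) -> list[dict]:
        rows = [dict(region=name, **scores)
                for name, scores in self.per_class.items()]
        rows.append(dict(region="bifurcation", **self.whole))
        return rows


def _scores(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dsc": dice(c),
        "mcc": mcc(c),
        "f2": f_beta_score(c, 2.0),
        "f05": f_beta_score(c, 0.5),
        "tpr": tpr(c),
    }


def evaluate(pred: LabelMap, truth: LabelMap) -> MetricsReport:
    """Score a predicted multi-class label map against ground truth.

    One-vs-rest scores for each branch class plus foreground-union
    ("whole bifurcation") scores, where an ICA/ECA class swap still
    scores perfectly because bulb-division disagreement is not counted.
    Both maps must share the grid and be cropped/standardized identically
    by the caller.
    """
    if not same_grid(pred, truth):
        raise ValueError("prediction and truth are on different grids")
    per_class = {}
    for code, name in CODE_TABLE.items():
        if code == 0:
            continue
        per_class[name] = _scores(confusion(pred.class_mask(code),
                                            truth.class_mask(code)))
    whole = _scores(confusion(pred.foreground(), truth.foreground()))
    return MetricsReport(per_class, whole)


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss kappa for a subjects x categories table of rating counts.

    Each row holds, for one subject, how many of the (fixed) n raters
    assigned each category; for the qualitative quality scale the
    categories are the five ordinal scores 0–4.  Returns NaN when chance
    agreement P_e equals 1 (every rater used a single category for every
    subject), where kappa is undefined.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("ratings must be a 2D subjects x categories table")
    if np.any(table < 0) or not np.allclose(table, np.rint(table)):
        raise ValueError("ratings must be non-negative integer counts")
    n_raters = table.sum(axis=1)
    if np.any(n_raters < 2):
        raise ValueError("every subject needs >= 2 ratings")
    if np.unique(n_raters).size != 1:
        raise ValueError("unequal rater counts per subject")
    p_cat = table.sum(axis=0) / table.sum()
    p_e = float(np.sum(p_cat**2))
    if np.isclose(p_e, 1.0):
        return float("nan")
    return float(_sm_fleiss_kappa(table, method="fleiss"))
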