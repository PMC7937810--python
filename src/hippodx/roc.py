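"""ROC analysis for scalar discriminators.

AUC is defined as the Mann-Whitney pair-ordering probability (ties count
0.5), computed from midranks so it agrees exactly with brute-force pair
counting.  The ROC curve is the monotone step function with one vertex per
distinct score, whose trapezoidal area equals that AUC.  The optimal
diagnostic cutoff maximizes Youden's J = sensitivity + specificity - 1, with
the reported reference value placed midway between the adjacent distinct
scores spanning the chosen operating point.

``direction`` states which tail is disease-like: for volumes the positive
(patient) class has *lower* scores; for a signed asymmetry index it depends
on the side of the lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DIRECTIONS = ("lower_is_positive", "higher_is_positive")


def _oriented(scores, labels, direction, positive_label):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    pos = labels == positive_label
    if pos.all() or not pos.any():
        raise ValueError("need both a positive and a negative class")
    # orient so that higher oriented score = more disease-like
    s = -scores if direction == "lower_is_positive" else scores.copy()
    return s, pos


def auc(scores, labels, direction: str = "lower_is_positive", positive_label=1) -> float:
    """Pair-ordering AUC: P(random positive ranks as more disease-like).

    Equals the fraction of (positive, negative) pairs ordered correctly in
    the oriented score, ties counting one half.
    """
    s, pos = _oriented(scores, labels, direction, positive_label)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(s)  # midranks handle ties exactly
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ROCResult:
    """Stepwise ROC curve with one vertex per distinct score.

    ``thresholds`` are in original score units, ordered from the most
    disease-like extreme; vertex 0 is (0,0) with an infinite threshold
    sentinel.  ``sens`` / ``one_minus_spec`` trace the curve to (1,1).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    one_minus_spec: np.ndarray
    auc: float
    direction: str
    n_pos: int
    n_neg: int

    def trapezoid_area(self) -> float:
        return float(np.trapezoid(self.sens, self.one_minus_spec))


def roc_points(scores, labels, direction: str = "lower_is_positive", positive_label=1) -> ROCResult:
    """Build the ROC step curve; its trapezoidal area equals :func:`auc`."""
    s, pos = _oriented(scores, labels, direction, positive_label)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    order = np.argsort(-s, kind="mergesort")
    s_sorted, pos_sorted = s[order], pos[order]
    # last index of each run of equal scores = vertex after that threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(pos_sorted)[distinct]
    fps = np.cumsum(~pos_sorted)[distinct]
    sens = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thr_oriented = np.r_[np.inf, s_sorted[distinct]]
    thresholds = -thr_oriented if direction == "lower_is_positive" else thr_oriented
    a = auc(scores, labels, direction, positive_label)
    return ROCResult(thresholds, sens, fpr, a, direction, n_pos, n_neg)


@dataclass
class CutoffRow:
    """One diagnostic-table row: reference value and operating point."""

    discriminator: str
    ref_value: float
    sens: float
    one_minus_spec: float
    auc: float
    task: str = ""
    direction: str = ""


def optimal_cutoff(roc: ROCResult, discriminator: str = "", task: str = "") -> CutoffRow:
    """Operating point maximizing Youden's J = sens - (1 - spec).

    Ties are broken toward higher sensitivity, then toward the reference
    value of smaller magnitude.  The reference value is the midpoint between
    the adjacent distinct scores spanning the chosen vertex (one half-step
    beyond the extreme scores for corner vertices).
    """
    j = roc.sens - roc.one_minus_spec
    if roc.thresholds.size < 2:
        raise ValueError("degenerate ROC curve")
    # oriented distinct scores, descending (skip the +inf sentinel)
    sign = -1.0 if roc.direction == "lower_is_positive" else 1.0
    s_desc = sign * roc.thresholds[1:]

    def ref_value(vertex: int) -> float:
        if vertex == 0:  # classify nothing positive: above the max score
            t = s_desc[0] + 1.0
        elif vertex == s_desc.size:  # classify everything positive
            t = s_desc[-1] - 1.0
        else:
            t = (s_desc[vertex - 1] + s_desc[vertex]) / 2.0
        return float(sign * t)

    best, key = None, None
    for v in range(roc.sens.size):
        cand = (j[v], roc.sens[v], -abs(ref_value(v)))
        if key is None or cand > key:
            best, key = v, cand
    return CutoffRow(
        discriminator=discriminator,
        ref_value=ref_value(best),
        sens=float(roc.sens[best]),
        one_minus_spec=float(roc.one_minus_spec[best]),
        auc=roc.auc,
        task=task,
        direction=roc.direction,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticROCResults:
    roc: ROCResult
    cutoff: CutoffRow

    @property
    def auc(self) -> float:
        return self.roc.auc

    def summary(self) -> str:
        c = self.cutoff
        return (
            f"Diagnostic ROC ({c.discriminator or 'score'}"
            + (f", {c.task}" if c.task else "")
            + f")\n  direction:    {self.roc.direction}\n"
            f"  n pos/neg:    {self.roc.n_pos}/{self.roc.n_neg}\n"
            f"  AUC:          {self.roc.auc:.3f}\n"
            f"  ref. value:   {c.ref_value:.4g}\n"
            f"  sensitivity:  {c.sens:.3f}\n"
            f"  1-specificity:{c.one_minus_spec:.3f}"
        )


class DiagnosticROC:
    """Model object for one scalar discriminator vs a binary outcome.

    Parameters
    ----------
    scores : array-like
        Discriminator values (volume, %TIV, asymmetry index, probability...).
    labels : array-like
        Class labels; ``positive_label`` marks the disease class.
    direction : str
        ``lower_is_positive`` (atrophy) or ``higher_is_positive``.
    """

    def __init__(self, scores, labels, direction="lower_is_positive",
                 positive_label=1, name: str = "", task: str = ""):
        self.scores = np.asarray(scores, dtype=float)
        self.labels = np.asarray(labels)
        self.direction = direction
        self.positive_label = positive_label
        self.name = name
        self.task = task

    def fit(self) -> DiagnosticROCResults:
        roc = roc_points(self.scores, self.labels, self.direction, self.positive_label)
        return DiagnosticROCResults(roc, optimal_cutoff(roc, self.name, self.task))


def diagnostic_table(feature_frame: pd.DataFrame, groups: pd.Series, tasks) -> pd.DataFrame:
    """Diagnostic cutoff table over many (discriminator, task) pairs.

    ``tasks`` is an iterable of dicts (or tuples) with keys ``column``,
    ``positive_group``, ``negative_group`` (default HC) and ``direction``.
    Returns one row per task with columns mirroring a published ROC table:
    discriminator, ref_value, sens, spec_1, auc, task.
    """
    rows = []
    for spec in tasks:
        if not isinstance(spec, dict):
            spec = dict(zip(("column", "positive_group", "direction", "negative_group"), spec))
        col = spec["column"]
        pos_g = spec["positive_group"]
        neg_g = spec.get("negative_group", "HC")
        direction = spec.get("direction", "lower_is_positive")
        if col not in feature_frame.columns:
            raise KeyError(f"unknown discriminator column {col!r}")
        for g in (pos_g, neg_g):
            if not (groups == g).any():
                raise ValueError(f"group {g!r} absent")
        mask = groups.isin([pos_g, neg_g])
        res = DiagnosticROC(
            feature_frame.loc[mask, col],
            groups.loc[mask],
            direction=direction,
            positive_label=pos_g,
            name=col,
            task=f"{pos_g}_vs_{neg_g}",
        ).fit()
        c = res.cutoff
        rows.append(
            dict(discriminator=col, ref_value=c.ref_value, sens=c.sens,
                 spec_1=c.one_minus_spec, auc=c.auc, task=c.task, direction=direction)
        )
    return pd.DataFrame(rows)
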