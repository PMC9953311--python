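"""Single-feature biomarker diagnostics.

ROC/AUC with the Mann-Whitney identity (ties count one half), exact
permutation significance at small sample sizes, and Pearson correlation
with the t-transform p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from cernet.dge import ValidationError

# exhaustive label-permutation enumeration is used up to this many
# case/control splits (12 choose 5 = 792 at the 7v5 design)
_MAX_EXACT_COMBINATIONS = 50_000


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: str  # "high_in_case" or "low_in_case"
    p_value: float
    p_method: str
    n_case: int
    n_control: int

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "p_value": self.p_value,
            "p_method": self.p_method,
            "orientation": self.orientation,
            "n_case": self.n_case,
            "n_control": self.n_control,
        }


def _auc_mann_whitney(case: np.ndarray, ctrl: np.ndarray) -> float:
    """U / (n1*n0) via midranks; ties contribute one half per pair."""
    n1, n0 = case.size, ctrl.size
    ranks = stats.rankdata(np.concatenate([case, ctrl]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _roc_points(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve at every distinct score threshold (predict case when
    score >= threshold), from (0,0) to (1,1); tie groups collapse to a
    single point, so the trapezoid area equals the Mann-Whitney AUC."""
    thresholds = np.unique(np.concatenate([case, ctrl]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for thr in thresholds:
        tpr.append(float((case >= thr).mean()))
        fpr.append(float((ctrl >= thr).mean()))
    return np.asarray(fpr), np.asarray(tpr)


def _exact_permutation_p(scores: np.ndarray, n_case: int, observed_auc: float) -> float:
    """Two-sided exact p for AUC != 0.5 by enumerating every assignment of
    case labels to the observed scores."""
    n = scores.size
    stat_obs = abs(observed_auc - 0.5)
    count = 0
    total = 0
    idx = np.arange(n)
    for case_idx in combinations(idx, n_case):
        mask = np.zeros(n, dtype=bool)
        mask[list(case_idx)] = True
        auc = _auc_mann_whitney(scores[mask], scores[~mask])
        if abs(auc - 0.5) >= stat_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def roc_auc(scores, labels, case_label="TAD") -> ROCResult:
    """ROC analysis of one score vector against binary labels.

    AUC is reported with auto-orientation (always >= 0.5) and the chosen
    polarity stated: "high_in_case" means larger scores look case-like,
    "low_in_case" means smaller scores do. The p-value tests AUC = 0.5,
    exactly by label permutation when the number of case/control splits
    is enumerable, else by normal approximation with tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size != labels.size:
        raise ValidationError("scores and labels differ in length")
    case_mask = labels == case_label
    n1, n0 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    case, ctrl = scores[case_mask], scores[~case_mask]
    auc_raw = _auc_mann_whitney(case, ctrl)
    if auc_raw >= 0.5:
        orientation = "high_in_case"
        oriented_case, oriented_ctrl = case, ctrl
        auc = auc_raw
    else:
        orientation = "low_in_case"
        oriented_case, oriented_ctrl = -case, -ctrl
        auc = 1.0 - auc_raw
    fpr, tpr = _roc_points(oriented_case, oriented_ctrl)

    if math.comb(n1 + n0, n1) <= _MAX_EXACT_COMBINATIONS:
        p = _exact_permutation_p(scores, n1, auc_raw)
        p_method = "exact_permutation"
    else:
        res = stats.mannwhitneyu(case, ctrl, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
        p_method = "normal_approximation"
    return ROCResult(auc, fpr, tpr, orientation, p, p_method, n1, n0)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y differ in length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValidationError("zero variance input")
    xm, ym = x - x.mean(), y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p
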