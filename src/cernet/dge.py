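"""Differential expression for one omics layer.

Per-feature log2 fold change, a two-sample test (Welch or an
empirical-Bayes moderated t with variances shrunk toward a pooled prior),
Benjamini-Hochberg adjustment, and threshold filtering into DEG lists.
Input matrices are assumed to already be on log2 scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

CASE_LABEL = "TAD"
CONTROL_LABEL = "CON"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class ExpressionDataset:
    """Log2 expression matrix with binary case/control labels.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Features x samples, log2 intensities.
    groups : pandas.Series
        One label per sample column; exactly two distinct labels with
        ``case_label`` marking cases.
    case_label : str
        Label identifying case samples (default ``"TAD"``).
    """

    matrix: pd.DataFrame
    groups: pd.Series
    case_label: str = CASE_LABEL

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if self.matrix.index.duplicated().any():
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature ids: {list(dupes[:5])}")
        if not self.matrix.columns.equals(self.groups.index):
            if set(self.matrix.columns) == set(self.groups.index):
                self.groups = self.groups.reindex(self.matrix.columns)
            else:
                raise ValidationError("sample ids of matrix and groups differ")
        labels = set(self.groups.unique())
        if self.case_label not in labels:
            raise ValidationError(
                f"case label {self.case_label!r} absent from groups {labels}"
            )
        if len(labels) != 2:
            raise ValidationError(f"need exactly 2 group labels, got {labels}")

    @property
    def case_mask(self) -> np.ndarray:
        return (self.groups == self.case_label).to_numpy()

    @property
    def n_case(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_control(self) -> int:
        return int((~self.case_mask).sum())

    def drop_incomplete_features(self) -> "ExpressionDataset":
        """Return a copy without features containing NaN/inf; logs the count."""
        finite = np.isfinite(self.matrix.to_numpy()).all(axis=1)
        n_dropped = int((~finite).sum())
        if n_dropped:
            logger.info("dropping %d features with missing values", n_dropped)
        return ExpressionDataset(
            self.matrix.loc[finite], self.groups, self.case_label
        )


@dataclass
class DEGThresholds:
    """Significance gate: p < p_threshold AND |logFC| > lfc_threshold (strict)."""

    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    use_adjusted_p: bool = False

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValidationError("thresholds must be positive")


def log2_fold_change(dataset: ExpressionDataset) -> pd.Series:
    """Per-feature logFC = mean(case) - mean(control), in log2 units."""
    case = dataset.case_mask
    if case.sum() == 0 or (~case).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    values = dataset.matrix.to_numpy(dtype=float)
    lfc = values[:, case].mean(axis=1) - values[:, ~case].mean(axis=1)
    return pd.Series(lfc, index=dataset.matrix.index, name="logFC")


def _welch(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t with Satterthwaite df; rows are features."""
    n1, n2 = case.shape[1], ctrl.shape[1]
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    # both-variances-zero convention: t=+/-inf (p=0), t=0/p=1 when means equal
    zero_se = se2 == 0
    if zero_se.any():
        delta = m1 - m2
        with np.errstate(invalid="ignore"):
            t = np.where(
                zero_se, np.where(delta == 0, 0.0, np.inf * np.sign(delta)), t
            )
        df = np.where(zero_se, 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((t == 0) & zero_se, 1.0, p)
    return t, p


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (limma's fitFDist helper)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # good starting value for trigamma inversion
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / y < 1e-8):
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on residual variances.

    Returns (d0, s0_squared); ``d0 = inf`` when the observed log-variances
    are less dispersed than pure chi-square sampling noise would imply.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1)
    tri_d = float(special.polygamma(1, df / 2.0))
    excess = var_z - tri_d
    if excess <= 0:
        # no evidence of variance heterogeneity: infinite prior df
        s0_sq = float(np.exp(e_z - special.digamma(df / 2.0) + np.log(df / 2.0)))
        return np.inf, s0_sq
    d0 = float(2.0 * _trigamma_inverse(np.array([excess]))[0])
    s0_sq = float(
        np.exp(
            e_z
            + special.digamma(d0 / 2.0)
            - special.digamma(df / 2.0)
            + np.log(df / d0)
        )
    )
    return d0, s0_sq


def _moderated(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated t with pooled-variance shrinkage.

    Posterior variance = (d0*s0^2 + d*s^2) / (d0 + d), t recomputed with
    d0 + d degrees of freedom; the prior (d0, s0^2) is fit by method of
    moments on the log residual variances.
    """
    n1, n2 = case.shape[1], ctrl.shape[1]
    d = n1 + n2 - 2
    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    s2 = (
        case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    ) / d
    d0, s0_sq = fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    zero = se == 0
    if zero.any():
        delta = m1 - m2
        with np.errstate(invalid="ignore"):
            t = np.where(
                zero, np.where(delta == 0, 0.0, np.inf * np.sign(delta)), t
            )
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((t == 0) & zero, 1.0, p)
    return t, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Standard step-up with monotonicity enforcement: adj_p[i] =
    min_{j: p_j >= p_i} (m * p_j / rank_j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def test_differential(
    dataset: ExpressionDataset, method: str = "moderated"
) -> pd.DataFrame:
    """Per-feature differential-expression table.

    Returns a DataFrame indexed by feature id with columns
    ``logFC, t, p, adj_p, direction`` (direction = sign of logFC,
    "up"/"down"; zero logFC reported as "up" by tie-break, never a DEG
    under a strict |logFC| gate anyway).
    """
    if method not in ("welch", "moderated"):
        raise ValidationError(f"unknown method {method!r}")
    dataset = dataset.drop_incomplete_features()
    case_mask = dataset.case_mask
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValidationError("need >= 2 samples per group for testing")
    values = dataset.matrix.to_numpy(dtype=float)
    case, ctrl = values[:, case_mask], values[:, ~case_mask]
    if method == "moderated" and values.shape[0] < 2:
        raise ValidationError("moderated test needs >= 2 features")
    if method == "welch":
        t, p = _welch(case, ctrl)
    else:
        t, p = _moderated(case, ctrl)
    if np.isinf(t).any():
        warnings.warn(
            "features with zero variance in both groups: p reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    table = pd.DataFrame(
        {
            "logFC": lfc,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
            "direction": np.where(lfc < 0, "down", "up"),
        },
        index=dataset.matrix.index,
    )
    table.index.name = "id"
    return table


def filter_degs(records: pd.DataFrame, thresholds: DEGThresholds) -> pd.DataFrame:
    """Apply the DEG gate: p (or adj_p) strictly below threshold AND
    |logFC| strictly above threshold. Returns the surviving rows."""
    p_col = "adj_p" if thresholds.use_adjusted_p else "p"
    keep = (records[p_col] < thresholds.p_threshold) & (
        records["logFC"].abs() > thresholds.lfc_threshold
    )
    return records.loc[keep]
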