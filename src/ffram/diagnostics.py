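"""Diagnostic-evaluation statistics: 2×2 metrics, ROC AUC, the DeLong
paired AUC comparison, Bland–Altman agreement and per-patient rollup.

Orientation is explicit everywhere: an FFR-like index flags disease when
*low* (``lower_is_positive=True``), a diameter-stenosis-like index when
*high*.  Mixing the two silently is the classic field bug, so no routine
ever infers orientation from the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DiagnosticSummary:
    """2×2 rates plus optional AUC with its 95% CI."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    n_pos: int
    n_neg: int
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None


def confusion_metrics(calls, truth) -> DiagnosticSummary:
    """Standard 2×2 diagnostic rates for binary calls against truth.

    Likelihood ratios are undefined-safe: perfect specificity reports
    ``lr_pos = inf``, perfect sensitivity ``lr_neg = 0``.
    """
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must have equal length")
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"truth contains no {missing} cases")
    tp = int((calls & truth).sum())
    tn = int((~calls & ~truth).sum())
    fp = int((calls & ~truth).sum())
    fn = int((~calls & truth).sum())
    sens = tp / n_pos
    spec = tn / n_neg
    return DiagnosticSummary(
        accuracy=(tp + tn) / (n_pos + n_neg),
        sensitivity=sens,
        specificity=spec,
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        lr_pos=sens / (1.0 - spec) if spec < 1.0 else float("inf"),
        lr_neg=(1.0 - sens) / spec if spec > 0.0 else float("inf"),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _oriented(scores, lower_is_positive: bool) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    return -scores if lower_is_positive else scores


def roc_auc(scores, truth, lower_is_positive: bool) -> float:
    """ROC area via the tie-corrected Mann–Whitney statistic.

    Equals the probability that a random diseased case scores more
    disease-like than a random non-diseased case, ties counting 1/2.
    """
    truth = np.asarray(truth, dtype=bool)
    s = _oriented(scores, lower_is_positive)
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[truth].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _structural_components(s: np.ndarray, truth: np.ndarray):
    """DeLong placement values: V10 per diseased, V01 per non-diseased."""
    x = s[truth][:, None]     # diseased
    y = s[~truth][None, :]    # non-diseased
    psi = (x > y).astype(float) + 0.5 * (x == y)
    return psi.mean(axis=1), psi.mean(axis=0)


@dataclass
class DeLongResult:
    """Paired comparison of two correlated ROC areas."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov: float
    z: float
    p: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


def auc_variance(scores, truth, lower_is_positive: bool) -> float:
    """DeLong variance of a single AUC estimate."""
    truth = np.asarray(truth, dtype=bool)
    v10, v01 = _structural_components(_oriented(scores, lower_is_positive), truth)
    m, n = v10.size, v01.size
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(
    scores_a,
    scores_b,
    truth,
    lower_is_positive_a: bool,
    lower_is_positive_b: bool,
) -> DeLongResult:
    """DeLong structural-components test for a paired AUC difference.

    Both indexes must score the same cases.  Returns each AUC with its
    normal-approximation 95% CI and the two-sided p-value for equality.
    """
    truth = np.asarray(truth, dtype=bool)
    sa = _oriented(scores_a, lower_is_positive_a)
    sb = _oriented(scores_b, lower_is_positive_b)
    if sa.shape != sb.shape or sa.shape != truth.shape:
        raise ValueError("scores and truth must be paired with equal length")
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    va10, va01 = _structural_components(sa, truth)
    vb10, vb01 = _structural_components(sb, truth)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    var_a = float(np.var(va10, ddof=1) / m + np.var(va01, ddof=1) / n)
    var_b = float(np.var(vb10, ddof=1) / m + np.var(vb01, ddof=1) / n)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(va10, vb10, ddof=1)[0, 1] / m)
    if n > 1:
        cov += float(np.cov(va01, vb01, ddof=1)[0, 1] / n)
    var_diff = max(var_a + var_b - 2.0 * cov, 0.0)
    diff = auc_a - auc_b
    if var_diff == 0.0:
        z, p = 0.0, 1.0
    else:
        z = diff / math.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    half = 1.959963984540054

    def ci(auc: float, var: float) -> tuple[float, float]:
        w = half * math.sqrt(max(var, 0.0))
        return (auc - w, auc + w)

    return DeLongResult(auc_a=auc_a, auc_b=auc_b, var_a=var_a, var_b=var_b,
                        cov=cov, z=float(z), p=float(p),
                        ci_a=ci(auc_a, var_a), ci_b=ci(auc_b, var_b))


@dataclass
class BlandAltman:
    """Agreement of paired measurements: bias ± limits of agreement."""

    bias: float
    sd: float
    loa_lower: float
    loa_upper: float


def bland_altman(x, y) -> BlandAltman:
    """Bias (mean of y − x), SD of differences, and 95% limits of agreement."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need at least 2 paired observations")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias=bias, sd=sd,
                       loa_lower=bias - 1.96 * sd, loa_upper=bias + 1.96 * sd)


@dataclass
class Correlation:
    r: float
    p: float


def pearson_r(x, y) -> Correlation:
    """Sample Pearson correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return Correlation(r=float(r), p=float(p))


def aggregate_per_patient(
    records: pd.DataFrame,
    score_orientations: dict[str, bool],
    ischemia_threshold: float = 0.80,
) -> pd.DataFrame:
    """Collapse per-vessel records to per-patient worst-vessel records.

    A patient is ischemic if *any* vessel has invasive FFR at or below
    the threshold.  Each continuous index keeps its worst vessel: the
    minimum for FFR-like indexes (``lower_is_positive=True``), the
    maximum for stenosis-like indexes.
    """
    if "patient_id" not in records.columns:
        raise ValueError("records need a patient_id column")
    agg: dict = {"ffr_invasive": "min"}
    for col, lower in score_orientations.items():
        if col in records.columns:
            agg[col] = "min" if lower else "max"
    out = records.groupby("patient_id", as_index=False).agg(agg)
    out["ischemic"] = out["ffr_invasive"] <= ischemia_threshold
    return out


def diagnostic_report(
    records: pd.DataFrame,
    indexes: dict[str, tuple[bool, float]],
    level: str = "per-vessel",
    ischemia_threshold: float = 0.80,
) -> pd.DataFrame:
    """Tidy table of diagnostic metrics, one row per index.

    ``indexes`` maps a score column to ``(lower_is_positive, call
    threshold)``; an FFR-like index calls positive at or below its
    threshold, a stenosis-like index at or above.
    """
    truth = (records["ffr_invasive"] <= ischemia_threshold).to_numpy()
    rows = []
    for col, (lower, thr) in indexes.items():
        if col not in records.columns:
            continue
        scores = records[col].to_numpy(dtype=float)
        calls = scores <= thr if lower else scores >= thr
        summ = confusion_metrics(calls, truth)
        auc = roc_auc(scores, truth, lower)
        var = auc_variance(scores, truth, lower)
        w = 1.959963984540054 * math.sqrt(max(var, 0.0))
        rows.append({
            "index": col, "threshold": thr, "level": level,
            "accuracy": summ.accuracy, "sens": summ.sensitivity,
            "spec": summ.specificity, "lr_pos": summ.lr_pos,
            "lr_neg": summ.lr_neg, "ppv": summ.ppv, "npv": summ.npv,
            "auc": auc, "ci_lo": auc - w, "ci_hi": auc + w,
            "n_pos": summ.n_pos, "n_neg": summ.n_neg,
        })
    return pd.DataFrame(rows)
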