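"""Agreement and diagnostic statistics: Pearson with Fisher-z CI,
ICC(2,1), Bland-Altman limits of agreement, ROC/AUC with bootstrap CI,
and the Youden-optimal operating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["AgreementResult", "RocResult", "pearson_ci", "icc",
           "bland_altman", "roc_auc", "youden_optimal", "agreement"]


@dataclass
class AgreementResult:
    r: float
    r_ci: tuple
    icc: float
    icc_ci: tuple
    bland_altman: dict

    def to_dict(self) -> dict:
        return {"pearson_r": self.r, "pearson_ci": list(self.r_ci),
                "icc": self.icc, "icc_ci": list(self.icc_ci),
                "bland_altman": self.bland_altman}


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple
    curve: np.ndarray            # (M, 2) ordered (fpr, tpr)
    thresholds: np.ndarray       # (M,) score >= threshold -> positive
    operating_point: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"auc": self.auc, "auc_ci": list(self.auc_ci),
                "curve": self.curve.tolist(),
                "thresholds": [None if not np.isfinite(t) else float(t)
                               for t in self.thresholds],
                "operating_point": self.operating_point}


def _paired(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    return x, y


def pearson_ci(x, y, level: float = 0.95):
    """Sample Pearson r with a Fisher-z confidence interval.

    The CI uses ``atanh(r) ± z * 1/sqrt(n-3)`` back-transformed.
    """
    x, y = _paired(x, y, 4)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        return r, (r, r)
    z = np.arctanh(r)
    zcrit = sps.norm.ppf(0.5 + level / 2)
    se = 1.0 / np.sqrt(len(x) - 3)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return r, (float(lo), float(hi))


def _icc_anova(x, y):
    """Two-way ANOVA mean squares for an n x 2 (subject x rater) table."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = data - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return n, k, msr, msc, mse


def icc(x, y, level: float = 0.95):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`` with k = 2,
    CI by the F-based interval (McGraw & Wong).
    """
    x, y = _paired(x, y, 4)
    n, k, msr, msc, mse = _icc_anova(x, y)
    if msr < 1e-15:
        raise ValueError("zero between-subject variance; ICC undefined")
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    est = float((msr - mse) / denom)
    if mse < 1e-15 and msc <= mse + 1e-15:
        return est, (est, est)  # perfect agreement: degenerate CI
    alpha = 1.0 - level
    a = k * est / (n * (1.0 - est)) if est < 1.0 else np.inf
    b = 1.0 + k * est * (n - 1) / (n * (1.0 - est)) if est < 1.0 else np.inf
    if not np.isfinite(a):
        return est, (est, est)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr)
    lower = min(lower, est)
    upper = max(upper, est)
    return est, (float(lower), float(upper))


def bland_altman(x, y) -> dict:
    """Mean difference, sample SD, and 95% limits of agreement for d = x - y."""
    x, y = _paired(x, y, 2)
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd_diff,
        "loa_low": mean_diff - 1.96 * sd_diff,
        "loa_high": mean_diff + 1.96 * sd_diff,
    }


def agreement(x, y, level: float = 0.95) -> AgreementResult:
    r, r_ci = pearson_ci(x, y, level)
    i, i_ci = icc(x, y, level)
    return AgreementResult(r, r_ci, i, i_ci, bland_altman(x, y))


def _auc_midrank(scores, labels) -> float:
    ranks = sps.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(scores, labels, ci_boot: int = 2000, seed: int = 0,
            level: float = 0.95) -> RocResult:
    """ROC curve and AUC with a seeded bootstrap percentile CI.

    AUC is the Mann-Whitney U statistic with midrank tie handling (equal
    to the trapezoidal area under the threshold-sweep curve).  The curve
    classifies ``score >= threshold`` as positive, sweeping the unique
    scores from +inf downward.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1D sequences of equal length")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC analysis")

    auc = _auc_midrank(scores, labels)

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    distinct = np.concatenate([np.diff(s_sorted) < 0, [True]])
    tps = np.cumsum(l_sorted)[distinct]
    fps = np.cumsum(~l_sorted)[distinct]
    tpr = np.concatenate([[0.0], tps / n1])
    fpr = np.concatenate([[0.0], fps / n0])
    thresholds = np.concatenate([[np.inf], s_sorted[distinct]])
    curve = np.column_stack([fpr, tpr])

    rng = np.random.default_rng(seed)
    boot = []
    n = len(scores)
    for _ in range(ci_boot):
        idx = rng.integers(0, n, n)
        lb = labels[idx]
        if lb.all() or not lb.any():
            continue
        boot.append(_auc_midrank(scores[idx], lb))
    if boot:
        lo, hi = np.percentile(boot, [100 * (0.5 - level / 2),
                                      100 * (0.5 + level / 2)])
        ci = (float(lo), float(hi))
    else:
        ci = (auc, auc)

    result = RocResult(auc, ci, curve, thresholds)
    result.operating_point = youden_optimal(result)
    return result


def youden_optimal(roc: RocResult) -> dict:
    """Operating point maximizing sensitivity + specificity - 1.

    Ties are broken by higher sensitivity, then lower threshold.
    """
    fpr, tpr = roc.curve[:, 0], roc.curve[:, 1]
    sens = tpr
    spec = 1.0 - fpr
    j = sens + spec - 1.0
    thr = roc.thresholds
    # lexicographic: max J, then max sensitivity, then min threshold
    best = 0
    for i in range(1, len(j)):
        if (j[i] > j[best] + 1e-12
                or (abs(j[i] - j[best]) <= 1e-12 and sens[i] > sens[best] + 1e-12)
                or (abs(j[i] - j[best]) <= 1e-12
                    and abs(sens[i] - sens[best]) <= 1e-12 and thr[i] < thr[best])):
            best = i
    return {"threshold": float(thr[best]), "sensitivity": float(sens[best]),
            "specificity": float(spec[best]), "youden_j": float(j[best])}
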