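"""Diagnostic-performance and agreement statistics.

ROC/AUC with Youden-optimal cutoffs (AUC by the Mann-Whitney formulation
with ties counted 1/2, confidence interval by DeLong's method), Pearson
correlation, intraclass correlation ICC(2,1) for continuous measurement
agreement, Cohen's and weighted kappa for categorical agreement, and
per-stage concordance from confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "AgreementResult",
    "roc_auc",
    "youden_index",
    "pearson_r",
    "icc",
    "kappa",
    "concordance_table",
]


@dataclass
class RocResult:
    """ROC summary: AUC with DeLong CI and the Youden-optimal operating point."""

    auc: float
    roc_points: np.ndarray  # (n, 2) of (fpr, tpr), both non-decreasing
    cutoff: float
    sensitivity: float
    specificity: float
    ci_95: tuple[float, float]

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class AgreementResult:
    """Agreement summary; only the fields relevant to the producing call are set."""

    icc: float | None = None
    icc_ci_95: tuple[float, float] | None = None
    kappa: float | None = None
    kappa_se: float | None = None
    kappa_weights: str | None = None
    confusion: np.ndarray | None = None
    categories: tuple | None = None
    per_class_concordance: dict | None = field(default=None)


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


def _mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    m = len(pos)
    return float((r_pos - m * (m + 1) / 2.0) / (m * len(neg)))


def _delong_variance(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    """DeLong variance of the AUC via placement values (midranks handle ties)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # V10_i: fraction of negatives below positive i (ties count 1/2)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels) -> RocResult:
    """ROC analysis of a continuous score against a binary label.

    The Youden-optimal cutoff uses the convention "positive if score >=
    cutoff", scanning all observed scores; ties in Youden resolve to the
    lower cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = _mann_whitney_auc(scores, labels)

    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    thresholds = np.unique(scores)  # ascending
    tpr = np.array([np.mean(scores[pos] >= t) for t in thresholds])
    fpr = np.array([np.mean(scores[~pos] >= t) for t in thresholds])
    youden = tpr - fpr
    k = int(np.argmax(youden))  # argmax takes the first (lowest) threshold on ties
    cutoff = float(thresholds[k])
    sens = float(tpr[k])
    spec = float(1.0 - fpr[k])

    roc_points = np.column_stack(
        [np.concatenate([[0.0], np.sort(fpr), [1.0]]),
         np.concatenate([[0.0], np.sort(tpr), [1.0]])]
    )
    var = _delong_variance(scores, labels, auc)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocResult(
        auc=auc,
        roc_points=roc_points,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        ci_95=ci,
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def icc(ratings: np.ndarray | pd.DataFrame) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is a subjects x raters table with no missing cells.  The 95%
    CI uses the F-distribution method.
    """
    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 5 or arr.shape[1] < 2:
        raise ValueError("need a subjects x raters table (>=5 subjects, >=2 raters)")
    if np.any(~np.isfinite(arr)):
        raise ValueError("ratings must not contain missing cells")
    import pingouin as pg

    n, k = arr.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": arr.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    )
    # the ICC(2,1) row is labelled ICC2 or ICC(A,1) depending on version
    mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
    row = table[mask].iloc[0]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    return AgreementResult(icc=float(row["ICC"]), icc_ci_95=(lo, hi))


def _weight_matrix(k: int, weights: str) -> np.ndarray:
    i = np.arange(k)
    diff = np.abs(i[:, None] - i[None, :])
    if weights == "none":
        return (diff == 0).astype(float)
    if weights == "linear":
        return 1.0 - diff / (k - 1)
    if weights == "quadratic":
        return 1.0 - (diff / (k - 1)) ** 2
    raise ValueError(f"unknown weighting {weights!r}")


def kappa(c1, c2, weights: str = "none", categories=None) -> AgreementResult:
    """Cohen's kappa (optionally linear/quadratic weighted) with asymptotic SE.

    Categories are taken in sorted order of the union of observed labels
    unless given explicitly (needed to weight unobserved in-between levels).
    """
    c1 = np.asarray(c1)
    c2 = np.asarray(c2)
    if c1.shape != c2.shape:
        raise ValueError("rating vectors must have the same length")
    if categories is None:
        categories = np.unique(np.concatenate([c1, c2]))
    categories = np.asarray(categories)
    k = len(categories)
    if k < 2:
        raise ValueError("need at least 2 categories")
    lut = {c: i for i, c in enumerate(categories)}
    i1 = np.array([lut[c] for c in c1])
    i2 = np.array([lut[c] for c in c2])
    n = len(c1)
    p = np.zeros((k, k))
    np.add.at(p, (i1, i2), 1.0)
    p /= n
    w = _weight_matrix(k, weights)
    pi = p.sum(axis=1)  # rater-1 marginals
    pj = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(pi, pj)).sum())
    if pe >= 1.0 - 1e-15:
        raise ValueError("degenerate marginals: chance agreement is 1")
    kap = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen-Everitt large-sample variance of weighted kappa
    wbar_i = w @ pj  # row weighted means
    wbar_j = w.T @ pi
    term = (
        w * (1.0 - pe) - (wbar_i[:, None] + wbar_j[None, :]) * (1.0 - po)
    ) ** 2
    var = ((p * term).sum() - (po * pe - 2 * pe + po) ** 2) / (n * (1.0 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    return AgreementResult(
        kappa=float(kap),
        kappa_se=se,
        kappa_weights=weights,
        confusion=(p * n).astype(int),
        categories=tuple(categories.tolist()),
    )


def concordance_table(true_stage, called_stage, categories=None) -> AgreementResult:
    """Confusion matrix (rows = true) and per-class concordance percentages."""
    true_stage = np.asarray(true_stage)
    called_stage = np.asarray(called_stage)
    if true_stage.shape != called_stage.shape:
        raise ValueError("vectors must have the same length")
    if categories is None:
        categories = np.unique(np.concatenate([true_stage, called_stage]))
    categories = np.asarray(categories)
    lut = {c: i for i, c in enumerate(categories)}
    try:
        it = np.array([lut[c] for c in true_stage])
        ic = np.array([lut[c] for c in called_stage])
    except KeyError as exc:
        raise ValueError(f"label outside the stage set: {exc}") from exc
    k = len(categories)
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (it, ic), 1)
    per_class = {}
    for i, c in enumerate(categories):
        row_total = confusion[i].sum()
        per_class[c] = 100.0 * confusion[i, i] / row_total if row_total else np.nan
    return AgreementResult(
        confusion=confusion,
        categories=tuple(categories.tolist()),
        per_class_concordance=per_class,
    )
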