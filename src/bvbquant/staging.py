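"""Feature standardisation, L1-penalised feature selection and stage calling.

The staging pipeline mirrors common radiomics practice: continuous features
are z-scored, an L1-penalised (lasso) logistic regression with 10-fold
cross-validated binomial deviance picks the informative features, and the
selected features are refit by unpenalised logistic regression on the raw
scale to obtain interpretable coefficients with standard errors.

The published combined staging score is

    Logit(P) = 2.327 * WT/D + 0.184 * AVI + 3.215 * FD - 5.871

on raw (unstandardised) features; ``combined_logit`` evaluates it and
``call_stage`` maps the continuous score to an ordinal stage through two
cut-points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureTable",
    "StagingModel",
    "PUBLISHED_MODEL",
    "LassoResult",
    "zscore",
    "inverse_zscore",
    "lasso_select",
    "combined_logit",
    "fit_stage_cuts",
    "call_stage",
]

MODEL_FEATURES = ("wt_d", "avi_deg", "fd")


@dataclass
class FeatureTable:
    """Per-patient feature matrix with optional z-score state.

    ``data`` holds one row per patient; ``feature_columns`` are the model
    features; ``stage_column`` names the ordinal stage label column (values
    "I"/"II"/"III") when present.  After :func:`zscore`, the per-column means
    and SDs used are stored so the transform can be inverted.
    """

    data: pd.DataFrame
    feature_columns: tuple[str, ...] = MODEL_FEATURES
    stage_column: str | None = "stage"
    z_scored: bool = False
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_columns if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing}")
        if self.data[list(self.feature_columns)].isna().any().any():
            raise ValueError("model feature columns must not contain missing values")

    def outcome(self, positive_stages=("II", "III")) -> np.ndarray:
        """Binary outcome vector: 1 for advanced stages (default II+III vs I)."""
        if self.stage_column is None or self.stage_column not in self.data.columns:
            raise ValueError("no stage column available for outcome derivation")
        return self.data[self.stage_column].isin(positive_stages).to_numpy(int)


@dataclass(frozen=True)
class StagingModel:
    """Logistic staging score: raw-scale coefficients plus intercept."""

    coefficients: dict[str, float]
    intercept: float
    published: bool = False


#: The published combined staging model (raw-scale WT/D, AVI in degrees, FD).
PUBLISHED_MODEL = StagingModel(
    coefficients={"wt_d": 2.327, "avi_deg": 0.184, "fd": 3.215},
    intercept=-5.871,
    published=True,
)


@dataclass
class LassoResult:
    """Penalised-path feature selection outcome.

    ``coefficients``/``standard_errors`` come from the unpenalised refit of
    the selected features on the raw scale, which is the form in which such
    models are reported clinically.
    """

    lambda_path: np.ndarray
    cv_deviance: np.ndarray
    lambda_opt: float
    selected_features: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    path_nonzeros: np.ndarray
    separation_flag: bool = False


def zscore(table: FeatureTable, ddof: int = 1) -> FeatureTable:
    """Z-score the model feature columns, storing the transform parameters.

    Uses the sample SD (``ddof=1``) by default, matching mainstream
    statistical packages; pass ``ddof=0`` for the population convention.
    """
    if table.z_scored:
        return table
    data = table.data.copy()
    means, sds = {}, {}
    for col in table.feature_columns:
        x = data[col].to_numpy(float)
        mu = float(x.mean())
        sd = float(x.std(ddof=ddof))
        if sd == 0:
            raise ValueError(f"zero-variance feature column {col!r}")
        data[col] = (x - mu) / sd
        means[col], sds[col] = mu, sd
    return replace(table, data=data, z_scored=True, means=means, sds=sds)


def inverse_zscore(table: FeatureTable) -> FeatureTable:
    """Undo :func:`zscore` using the stored per-column means and SDs."""
    if not table.z_scored:
        return table
    data = table.data.copy()
    for col in table.feature_columns:
        data[col] = data[col] * table.sds[col] + table.means[col]
    return replace(table, data=data, z_scored=False, means={}, sds={})


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _l1_logistic(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # glmnet-style objective (1/n) sum loss + lam * ||w||_1  <=>  C = 1/(n*lam)
    clf = LogisticRegression(
        l1_ratio=1.0,
        C=1.0 / (len(y) * lam),
        solver="liblinear",
        tol=1e-10,
        max_iter=50000,
        random_state=0,
    )
    clf.fit(X, y)
    return clf


def lasso_select(
    table: FeatureTable,
    outcome: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 40,
    lambda_min_ratio: float = 1e-3,
) -> LassoResult:
    """L1-penalised logistic feature selection with cross-validated deviance.

    Features are z-scored, a log-spaced penalty path is walked with
    coordinate-descent L1 logistic fits, the penalty minimising the mean
    held-out binomial deviance over stratified folds is chosen, and the
    features surviving at that penalty are refit unpenalised on the raw scale
    (statsmodels) for coefficients, standard errors and p-values.
    """
    if outcome is None:
        outcome = table.outcome()
    y = np.asarray(outcome, dtype=int)
    if len(y) < folds * 2:
        raise ValueError(f"need at least {folds * 2} rows for {folds}-fold CV")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    zt = zscore(table)
    X = zt.data[list(table.feature_columns)].to_numpy(float)
    n = len(y)

    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
    lambda_path = np.logspace(
        np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), n_lambda
    )

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, n_lambda))
    for fi, (tr, te) in enumerate(cv.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise ValueError("both outcome classes must be present in every fold")
        for li, lam in enumerate(lambda_path):
            clf = _l1_logistic(X[tr], y[tr], lam)
            p = clf.predict_proba(X[te])[:, 1]
            dev[fi, li] = _binomial_deviance(y[te], p)
    cv_deviance = dev.mean(axis=0)
    li_opt = int(np.argmin(cv_deviance))
    lambda_opt = float(lambda_path[li_opt])

    path_nonzeros = np.array(
        [np.count_nonzero(_l1_logistic(X, y, lam).coef_) for lam in lambda_path]
    )
    full = _l1_logistic(X, y, lambda_opt)
    nz = np.nonzero(full.coef_.ravel())[0]
    selected = tuple(table.feature_columns[i] for i in nz)

    coefficients: dict[str, float] = {}
    standard_errors: dict[str, float] = {}
    p_values: dict[str, float] = {}
    separation = False
    if selected:
        raw = inverse_zscore(zt)
        X_raw = sm.add_constant(raw.data[list(selected)].to_numpy(float))
        with warnings.catch_warnings():
            warnings.simplefilter("always")
            try:
                fit = sm.Logit(y, X_raw).fit(disp=0, maxiter=200)
            except Exception:
                separation = True
                fit = sm.Logit(y, X_raw).fit_regularized(alpha=1e-6, disp=0)
        params = np.asarray(fit.params)
        bse = np.asarray(getattr(fit, "bse", np.full(len(params), np.nan)))
        pvals = np.asarray(getattr(fit, "pvalues", np.full(len(params), np.nan)))
        if np.any(~np.isfinite(bse)) or np.any(bse > 1e3):
            separation = True
        coefficients["intercept"] = float(params[0])
        standard_errors["intercept"] = float(bse[0])
        p_values["intercept"] = float(pvals[0])
        for k, name in enumerate(selected, start=1):
            coefficients[name] = float(params[k])
            standard_errors[name] = float(bse[k])
            p_values[name] = float(pvals[k])
    if separation:
        warnings.warn(
            "quasi-separation in the unpenalised refit; coefficients unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    return LassoResult(
        lambda_path=lambda_path,
        cv_deviance=cv_deviance,
        lambda_opt=lambda_opt,
        selected_features=selected,
        coefficients=coefficients,
        standard_errors=standard_errors,
        p_values=p_values,
        path_nonzeros=path_nonzeros,
        separation_flag=separation,
    )


def combined_logit(
    wt_d, avi_deg, fd, model: StagingModel = PUBLISHED_MODEL
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Evaluate the combined staging score; returns (logit, probability).

    Inputs are raw-scale: WT/D dimensionless, AVI in degrees, FD
    dimensionless.  Accepts scalars or arrays.
    """
    wt_d = np.asarray(wt_d, dtype=float)
    avi_deg = np.asarray(avi_deg, dtype=float)
    fd = np.asarray(fd, dtype=float)
    if not (np.all(np.isfinite(wt_d)) and np.all(np.isfinite(avi_deg)) and np.all(np.isfinite(fd))):
        raise ValueError("inputs must be finite")
    c = model.coefficients
    logit = c["wt_d"] * wt_d + c["avi_deg"] * avi_deg + c["fd"] * fd + model.intercept
    prob = 1.0 / (1.0 + np.exp(-logit))
    if logit.ndim == 0:
        return float(logit), float(prob)
    return logit, prob


def fit_stage_cuts(logits: np.ndarray, stages) -> tuple[float, float]:
    """Fit two ordinal cut-points on the logit maximising staging concordance.

    Scans midpoints between adjacent sorted scores for both cuts and picks
    the ordered pair (cut1 < cut2) with the highest overall agreement with
    the given stage labels; ties resolve to the lowest cuts (deterministic).
    """
    logits = np.asarray(logits, dtype=float)
    stages = np.asarray(stages)
    order = {"I": 0, "II": 1, "III": 2}
    truth = np.array([order[str(s)] for s in stages])
    uniq = np.unique(logits)
    cands = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = (-1.0, None)
    for i, c1 in enumerate(cands):
        called1 = logits >= c1
        for c2 in cands[i + 1:]:
            called = called1.astype(int) + (logits >= c2)
            acc = float(np.mean(called == truth))
            if acc > best[0] + 1e-12:
                best = (acc, (float(c1), float(c2)))
    return best[1]


def call_stage(logits, cuts: tuple[float, float]):
    """Map combined-logit scores to ordinal stages via two ordered cuts."""
    c1, c2 = cuts
    if not c1 < c2:
        raise ValueError("cuts must satisfy cut1 < cut2")
    logits = np.atleast_1d(np.asarray(logits, dtype=float))
    idx = (logits >= c1).astype(int) + (logits >= c2).astype(int)
    labels = np.array(["I", "II", "III"])[idx]
    return labels if len(labels) > 1 else labels[0]
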