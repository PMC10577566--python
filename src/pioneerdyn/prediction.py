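"""Lasso-logistic prediction of downregulated genes and resampled ROC/AUC.

Per-gene kernel-weighted peak sums by category form the predictor matrix;
the outcome is downregulated vs expression-matched stable. The penalty is
chosen by minimum k-fold cross-validated binomial deviance along a
log-spaced lambda path (features standardized internally; coefficients
returned on the original scale). ROC curves are built over all score
thresholds with tied scores grouped; AUC is the trapezoidal area (equal to
the Mann-Whitney U statistic over n1*n2); the operating point is the
maximum-accuracy threshold with ties resolved toward specificity. The
pipeline repeats the fit over many matched-control resamples, scoring
either out-of-fold (default) or in-sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .matching import match_genes_expression

__all__ = [
    "LogitModel",
    "ROCResult",
    "fit_logistic_lasso",
    "roc_auc",
    "cv_deviance",
    "predict_deg_pipeline",
]


@dataclass
class LogitModel:
    intercept: float
    coefficients: pd.Series
    lam: float
    cv_curve: pd.DataFrame = field(default_factory=pd.DataFrame)
    separation_warning: bool = False

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return expit(self.intercept + Xa @ self.coefficients.to_numpy())


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    max_acc_threshold: float
    tpr_at_max_acc: float
    fpr_at_max_acc: float
    resample_aucs: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced path from the smallest lambda nulling all coefficients."""
    n = len(y)
    r = y - y.mean()
    lam_max = np.abs(X.T @ r).max() / n
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> tuple[float, np.ndarray]:
    """L1-penalized logistic fit at one penalty (saga; unpenalized intercept,
    the glmnet convention). lambda relates to sklearn's C by C = 1/(n*lambda).
    """
    import warnings

    n = len(y)
    C = 1.0 / (n * lam)
    clf = LogisticRegression(
        penalty="l1", C=C, solver="saga", tol=1e-7, max_iter=5000, random_state=0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def cv_deviance(
    X: np.ndarray, y: np.ndarray, cv_folds: int = 5, seed: int = 0,
    n_lambdas: int = 30,
) -> float:
    """Minimum CV binomial deviance over the lambda path (used by sweeps)."""
    model = fit_logistic_lasso(X, y, cv_folds=cv_folds, seed=seed, n_lambdas=n_lambdas)
    return float(model.cv_curve["cv_deviance"].min())


def fit_logistic_lasso(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    lambda_path: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 100,
) -> LogitModel:
    """Lasso-logistic fit with penalty chosen by minimum CV deviance.

    Standardization is internal; returned coefficients are on the input
    scale, so the selected penalty is invariant to feature scaling.
    """
    feature_names = (
        list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    )
    Xa = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant")
    if not np.isfinite(Xa).all():
        raise ValueError("features must be finite")
    Xs, mean, sd = _standardize(Xa)
    path = lambda_path if lambda_path is not None else _lambda_path(Xs, y, n_lambdas)

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xs, y))
    dev = np.zeros(len(path))
    for tr, te in folds:
        for j, lam in enumerate(path):
            b0, b = _fit_l1(Xs[tr], y[tr], lam)
            p = expit(b0 + Xs[te] @ b)
            dev[j] += _binomial_deviance(y[te], p)
    best_j = int(np.argmin(dev))
    lam = float(path[best_j])
    b0, b = _fit_l1(Xs, y, lam)
    # back-transform to the original feature scale
    coef = b / sd
    intercept = b0 - float(np.dot(coef, mean))
    return LogitModel(
        intercept=intercept,
        coefficients=pd.Series(coef, index=feature_names),
        lam=lam,
        cv_curve=pd.DataFrame({"lambda": path, "cv_deviance": dev}),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC over all thresholds with tie grouping; trapezoidal AUC.

    The max-accuracy threshold is the score cutoff (predict positive when
    score >= threshold) maximizing (TP + TN)/n; ties resolve to the higher
    threshold (toward specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    ylab = labels[order]
    # group tied scores
    boundary = np.flatnonzero(np.diff(s)) + 1
    groups = np.split(np.arange(len(s)), boundary)
    tp = fp = 0
    tprs, fprs, thr = [0.0], [0.0], [np.inf]
    for grp in groups:
        tp += int(ylab[grp].sum())
        fp += len(grp) - int(ylab[grp].sum())
        tprs.append(tp / n_pos)
        fprs.append(fp / n_neg)
        thr.append(float(s[grp[0]]))
    tpr = np.asarray(tprs)
    fpr = np.asarray(fprs)
    thresholds = np.asarray(thr)
    auc = float(np.trapezoid(tpr, fpr))
    acc = (tpr * n_pos + (1 - fpr) * n_neg) / (n_pos + n_neg)
    best = int(np.flatnonzero(acc == acc.max())[0])  # first = highest threshold
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        max_acc_threshold=float(thresholds[best]),
        tpr_at_max_acc=float(tpr[best]),
        fpr_at_max_acc=float(fpr[best]),
    )


def _out_of_fold_scores(
    X: np.ndarray, y: np.ndarray, lam: float, cv_folds: int, seed: int
) -> np.ndarray:
    scores = np.empty(len(y))
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        Xs, mean, sd = _standardize(X[tr])
        b0, b = _fit_l1(Xs, y[tr], lam)
        scores[te] = b0 + ((X[te] - mean) / sd) @ b
    return scores


def predict_deg_pipeline(
    features: pd.DataFrame,
    feature_sets: dict[str, list[str]],
    cases: pd.Series,
    control_pool: pd.Series,
    n_resample: int = 100,
    cv_folds: int = 5,
    seed: int = 0,
    in_sample: bool = False,
    alpha: float = 0.05,
) -> dict[str, ROCResult]:
    """Resampled matched-control prediction for several feature sets.

    `features` is the gene-by-category weighted-sum table; `cases` /
    `control_pool` are expression series for downregulated and stable
    genes. For each of `n_resample` KS-accepted control draws a lasso
    model is fit per feature set and scored (out-of-fold by default); the
    returned ROCResult per feature set is computed on the pooled scores of
    the final resample, with per-resample AUCs in `resample_aucs`, plus a
    per-resample max-accuracy TPR/FPR table attached as `.operating_points`.
    """
    draws = match_genes_expression(
        cases, control_pool, n_draws=n_resample, alpha=alpha, seed=seed
    )
    out: dict[str, ROCResult] = {}
    for set_name, cols in feature_sets.items():
        aucs = np.empty(n_resample)
        op_rows = []
        last_roc: ROCResult | None = None
        for r, draw in enumerate(draws):
            ids = list(cases.index) + draw.control_ids
            y = np.array([1] * len(cases) + [0] * len(draw.control_ids))
            X = features.loc[ids, cols].to_numpy(float)
            model = fit_logistic_lasso(
                features.loc[ids, cols], y, cv_folds=cv_folds, seed=seed + r,
                n_lambdas=30,
            )
            if in_sample:
                scores = model.predict_proba(X)
            else:
                scores = _out_of_fold_scores(X, y, model.lam, cv_folds, seed + r)
            roc = roc_auc(scores, y)
            aucs[r] = roc.auc
            op_rows.append(
                (r, roc.auc, roc.tpr_at_max_acc, roc.fpr_at_max_acc)
            )
            last_roc = roc
        assert last_roc is not None
        last_roc.resample_aucs = aucs
        last_roc.operating_points = pd.DataFrame(  # type: ignore[attr-defined]
            op_rows, columns=["resample", "auc", "tpr_at_max_acc", "fpr_at_max_acc"]
        )
        out[set_name] = last_roc
    return out
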