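"""Leave-one-subject-out logistic classification and screening metrics.

Every modelling step that looks at the data — z-scoring, Davies-Bouldin
feature selection, the logistic fit — is refit inside each fold on the
training subjects only, so the held-out subject never influences the
model that scores it.

The logistic regression is an unregularised maximum-likelihood fit by
iteratively reweighted least squares (IRLS).  With ~60 subjects and 10
selected predictors complete separation is a real possibility
(especially under permuted labels); when detected, the fold refits with
a small ridge penalty (lambda = 1e-4) and flags it, keeping every fold's
coefficients finite.

Metrics follow the standard screening definitions: a subject is called
positive when its out-of-fold score >= tau (default 0.5), sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP).  The ROC curve sweeps all distinct
score thresholds; AUC is the trapezoidal area, which equals the
pair-counting (rank-sum) concordance with half credit for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .selection import SelectionError, db_scores

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizeParams:
    mean: pd.Series
    sd: pd.Series  # sample SD (n-1 divisor); zero marks a degenerate column

    @property
    def degenerate(self) -> list[str]:
        return list(self.sd.index[self.sd == 0])


def standardize_fit(X: pd.DataFrame) -> StandardizeParams:
    """Per-feature mean and sample SD from a training set."""
    if len(X) == 0:
        raise EvaluationError("empty training set")
    sd = X.std(ddof=1).fillna(0.0)
    return StandardizeParams(mean=X.mean(), sd=sd)


def standardize_apply(X: pd.DataFrame, params: StandardizeParams) -> pd.DataFrame:
    """z-score ``X`` using training parameters only.  Zero-SD (constant
    in training) columns map to 0 so they carry no information."""
    sd = params.sd.replace(0.0, np.inf)
    return (X - params.mean) / sd


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    intercept: float
    coef: pd.Series
    converged: bool
    separation_fallback: bool
    ridge: float

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Xv = X[self.coef.index].to_numpy(float)
        return self.intercept + Xv @ self.coef.to_numpy()


def fit_logistic(
    X: pd.DataFrame,
    y,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_ridge: float = 1e-4,
) -> LogisticModel:
    """Maximum-likelihood logistic fit with a ridge fallback.

    The Newton/IRLS iteration stops when the max parameter update falls
    below ``tol``.  Separation is declared when the iteration fails to
    converge, a coefficient diverges, or the Hessian becomes singular;
    the model is then refit from zero with ``separation_ridge`` added to
    the (non-intercept) penalty.
    """
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise EvaluationError("labels must be binary 0/1")
    if len(np.unique(yv)) < 2:
        raise EvaluationError("both classes must be present to fit")

    Xv = X.to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(Xv)), Xv])
    beta, converged, fallback, ridge = _fit_design(
        design, yv, ridge, tol, max_iter, separation_ridge
    )
    return LogisticModel(
        intercept=float(beta[0]),
        coef=pd.Series(beta[1:], index=X.columns),
        converged=converged,
        separation_fallback=fallback,
        ridge=ridge,
    )


_warned_separation = False


def _fit_design(design, y, ridge, tol, max_iter, separation_ridge):
    """ML fit on a prebuilt design matrix; returns (beta, converged,
    fallback_used, effective_ridge)."""
    m = design.shape[1]
    pen = np.full(m, ridge)
    pen[0] = 0.0
    beta, converged, failed = _irls(design, y, pen, tol, max_iter)
    fallback = False
    if failed or not converged or np.max(np.abs(beta)) > 50.0:
        fallback = True
        ridge = max(ridge, separation_ridge)
        pen = np.full(m, ridge)
        pen[0] = 0.0
        beta, converged, failed = _irls(design, y, pen, tol, max_iter)
        # warn once per process, then demote to debug to keep permutation
        # loops readable
        global _warned_separation
        if not _warned_separation:
            logger.warning("separation detected; refit with ridge lambda=%g",
                           ridge)
            _warned_separation = True
        else:
            logger.debug("separation detected; refit with ridge lambda=%g",
                         ridge)
        if failed:
            raise EvaluationError("logistic fit failed even with ridge fallback")
    return beta, converged, fallback, ridge


def _irls(design, y, pen, tol, max_iter):
    m = design.shape[1]
    beta = np.zeros(m)
    for _ in range(max_iter):
        eta = design @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = design.T @ (y - mu) - pen * beta
        hess = (design.T * w) @ design + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False, True
        if not np.all(np.isfinite(step)):
            return beta, False, True
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True, False
        # coefficients running away marks (quasi-)separation; stop early
        if np.max(np.abs(beta)) > 50.0:
            return beta, False, False
    return beta, False, False


def predict_score(model: LogisticModel, X: pd.DataFrame) -> np.ndarray:
    """Class-1 probability for each row."""
    return expit(model.linear_predictor(X))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    sensitivity_defined: bool = True
    specificity_defined: bool = True

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def error_rate(self) -> float:
        return 1.0 - self.accuracy

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "n": self.n,
        }


def classification_metrics(scores, labels, tau: float = 0.5) -> Metrics:
    """Confusion counts and rates at score threshold ``tau`` (a score
    equal to the threshold counts as a positive call).  With no actual
    positives (negatives) the undefined sensitivity (specificity) is
    reported as 0 and flagged."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise EvaluationError("scores and labels must be aligned")
    pred = s >= tau
    pos = y == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    n = len(y)
    sens_def = (tp + fn) > 0
    spec_def = (tn + fp) > 0
    return Metrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if sens_def else 0.0,
        specificity=tn / (tn + fp) if spec_def else 0.0,
        sensitivity_defined=sens_def,
        specificity_defined=spec_def,
    )


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC over all distinct score thresholds (descending),
    starting at (0, 0) with an effectively infinite threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise EvaluationError("ROC requires both classes")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted == 1)[distinct]
    fps = np.cumsum(y_sorted == 0)[distinct]
    return RocCurve(
        fpr=np.r_[0.0, fps / n0],
        tpr=np.r_[0.0, tps / n1],
        thresholds=np.r_[np.inf, s_sorted[distinct]],
    )


def auc_trapezoid(roc: RocCurve) -> float:
    return float(np.trapezoid(roc.tpr, roc.fpr))


def auc_pair_count(scores, labels) -> float:
    """Concordance probability: over all case/control pairs the fraction
    in which the case scores higher, with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    s1 = s[y == 1]
    s0 = s[y == 0]
    if s1.size == 0 or s0.size == 0:
        raise EvaluationError("AUC requires both classes")
    diff = s1[:, None] - s0[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def roc_auc(scores, labels) -> tuple[RocCurve, float]:
    roc = roc_curve(scores, labels)
    return roc, auc_trapezoid(roc)


# ---------------------------------------------------------------------------
# leave-one-subject-out evaluation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    subject_ids: list
    labels: np.ndarray
    scores: np.ndarray
    tau: float
    metrics: Metrics
    roc: RocCurve
    auc: float
    fold_features: list[list[str]]
    fold_fallbacks: int

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def error_rate(self) -> float:
        return self.metrics.error_rate

    @property
    def n_incorrect(self) -> int:
        return self.metrics.fp + self.metrics.fn

    def feature_selection_counts(self) -> pd.Series:
        """How many folds selected each feature (descending)."""
        counts: dict[str, int] = {}
        for feats in self.fold_features:
            for f in feats:
                counts[f] = counts.get(f, 0) + 1
        return pd.Series(counts).sort_values(ascending=False)

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "tau": self.tau,
            "scores": {str(s): float(v)
                       for s, v in zip(self.subject_ids, self.scores)},
            "metrics": self.metrics.to_dict(),
            "auc": self.auc,
            "feature_selection_counts":
                {k: int(v) for k, v in self.feature_selection_counts().items()},
            "separation_fallback_folds": self.fold_fallbacks,
        }


def loso_evaluate(
    X: pd.DataFrame,
    labels,
    k: int = 10,
    tau: float = 0.5,
    q: int = 1,
) -> CvResult:
    """Leave-one-subject-out cross-validated logistic classification.

    For each of the n subjects: fit z-scoring parameters on the other
    n-1, Davies-Bouldin-rank the standardized features, keep the best
    ``k``, fit the logistic model, and score the held-out subject with
    the training fold's z-parameters.  Returns one out-of-fold score per
    subject plus metrics at threshold ``tau`` and the ROC/AUC.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise EvaluationError("need at least 3 subjects for LOSO")
    if X.shape[0] != n:
        raise EvaluationError("feature table and labels misaligned")
    if len(np.unique(y)) < 2:
        raise EvaluationError("both classes must be present")
    if k > X.shape[1]:
        raise SelectionError(f"k={k} exceeds feature count {X.shape[1]}")

    from .selection import _db_scores_matrix

    Xv = X.to_numpy(dtype=float)
    cols = list(X.columns)
    yv = y.astype(float)
    scores = np.empty(n)
    fold_features: list[list[str]] = []
    fallbacks = 0

    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        ytr = yv[mask]
        m1 = ytr == 1
        if m1.all() or not m1.any():
            raise EvaluationError(
                f"training set for fold {i} contains a single class; "
                "cannot fit a leakage-safe model"
            )
        Xtr = Xv[mask]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        safe_sd = np.where(sd > 0, sd, np.inf)
        Ztr = (Xtr - mu) / safe_sd

        db = _db_scores_matrix(Ztr, ~m1, m1, q)
        order = np.argsort(db, kind="stable")[:k]
        fold_features.append([cols[j] for j in order])

        design = np.column_stack([np.ones(n - 1), Ztr[:, order]])
        beta, _, fallback, _ = _fit_design(design, ytr, 0.0, 1e-8, 100, 1e-4)
        fallbacks += fallback

        z_test = (Xv[i] - mu) / safe_sd
        scores[i] = expit(beta[0] + z_test[order] @ beta[1:])

    metrics = classification_metrics(scores, y, tau=tau)
    roc, auc = roc_auc(scores, y)
    return CvResult(
        subject_ids=list(X.index),
        labels=y,
        scores=scores,
        tau=tau,
        metrics=metrics,
        roc=roc,
        auc=auc,
        fold_features=fold_features,
        fold_fallbacks=fallbacks,
    )
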