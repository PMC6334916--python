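"""Univariate Davies-Bouldin feature selection for two diagnostic groups.

Each feature is scored independently by the two-cluster Davies-Bouldin
ratio

    DB = (S_case + S_control) / |c_case - c_control|

where c_i is the class mean and S_i the within-class scatter: the mean
absolute deviation from the class mean by default (scatter exponent
q = 1 in the classical formulation; q = 2, the RMS scatter, is
available).  Lower scores mean better-separated classes; zero centroid
separation maps to +inf so such features rank last.  Selection keeps
the k lowest-scoring features with a stable tie-break on the original
column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


def _class_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise SelectionError(
            f"need exactly two classes, got {classes.size} ({classes!r})"
        )
    return y == classes[0], y == classes[1]


def db_index(values, labels, q: int = 1) -> float:
    """Davies-Bouldin score of a single feature against binary labels."""
    x = np.asarray(values, dtype=float)
    m0, m1 = _class_masks(labels)
    return float(_db_scores_matrix(x[:, None], m0, m1, q)[0])


def db_scores(X, labels, q: int = 1) -> pd.Series:
    """Vectorised per-feature Davies-Bouldin scores.

    Parameters
    ----------
    X:
        (n_subjects, n_features) array or DataFrame.
    labels:
        Binary labels, one per subject.
    """
    m0, m1 = _class_masks(labels)
    if isinstance(X, pd.DataFrame):
        return pd.Series(_db_scores_matrix(X.to_numpy(float), m0, m1, q),
                         index=X.columns)
    return pd.Series(_db_scores_matrix(np.asarray(X, float), m0, m1, q))


def _db_scores_matrix(X: np.ndarray, m0, m1, q: int) -> np.ndarray:
    if q not in (1, 2):
        raise SelectionError("scatter exponent q must be 1 or 2")
    c0 = X[m0].mean(axis=0)
    c1 = X[m1].mean(axis=0)
    d0 = X[m0] - c0
    d1 = X[m1] - c1
    if q == 1:
        s0 = np.abs(d0).mean(axis=0)
        s1 = np.abs(d1).mean(axis=0)
    else:
        s0 = np.sqrt((d0**2).mean(axis=0))
        s1 = np.sqrt((d1**2).mean(axis=0))
    sep = np.abs(c0 - c1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(sep > 0, (s0 + s1) / sep, np.inf)
    # zero scatter with zero separation is indistinguishable classes
    scores = np.where((sep == 0), np.inf, scores)
    return scores


@dataclass
class SelectionResult:
    """Ranked features with their DB scores and the chosen subset."""

    ranking: list[str]
    scores: pd.Series
    selected: list[str]

    @property
    def k(self) -> int:
        return len(self.selected)

    def to_records(self) -> list[dict]:
        rank_of = {name: r for r, name in enumerate(self.ranking, start=1)}
        return [
            {
                "feature": name,
                "db_score": None if np.isinf(s) else float(s),
                "rank": rank_of[name],
                "selected": name in set(self.selected),
            }
            for name, s in self.scores.items()
        ]


def select_top_features(X: pd.DataFrame, labels, k: int = 10,
                        q: int = 1) -> SelectionResult:
    """Keep the ``k`` features with the smallest DB scores.

    ``X`` is expected to be standardized on the same subjects used for
    scoring (the DB score itself is affine-invariant, so this affects
    nothing but interpretability of the scores).  Ties and +inf scores
    break by original column order (stable sort), so the ranking is a
    reproducible permutation of the columns.
    """
    if k > X.shape[1]:
        raise SelectionError(f"k={k} exceeds feature count {X.shape[1]}")
    scores = db_scores(X, labels, q=q)
    order = np.argsort(scores.to_numpy(), kind="stable")
    ranking = [X.columns[i] for i in order]
    return SelectionResult(ranking=ranking, scores=scores, selected=ranking[:k])
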