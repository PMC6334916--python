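"""Questionnaire comparator: CBCL T-score cutoff screening.

The Child Behavior Checklist (CBCL) yields normed T scores per scale;
the conventional clinical cutoff is T >= 70 and a more liberal
screening cutoff is T >= 55.  This module classifies subjects by such
cutoffs against the clinical diagnosis label and computes the
threshold-free AUC using the continuous T score as the ranking
statistic.

Missing T scores are excluded listwise per scale; because the original
per-scale denominators are not recoverable from summary tables, every
result carries the number of subjects actually analysed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import Metrics, classification_metrics, roc_auc

#: scales shared by the preschool and school-age CBCL forms
SCALES = ("internalizing", "anxiety_problems", "depressive_problems")

CLINICAL_CUTOFF = 70.0
SCREENING_CUTOFF = 55.0


class CbclError(ValueError):
    pass


def cutoff_classify(t_scores, cutoff: float) -> np.ndarray:
    """Binary screen: positive iff T >= cutoff (inclusive).  Input must
    already be missing-free."""
    t = np.asarray(t_scores, dtype=float)
    if t.size == 0 or np.any(np.isnan(t)):
        raise CbclError("t_scores must be non-empty and missing-free")
    return (t >= cutoff).astype(int)


def _complete_cases(records: pd.DataFrame, scale: str) -> pd.DataFrame:
    if scale not in records.columns:
        raise CbclError(f"scale {scale!r} not in records")
    sub = records[[scale, "diagnosis"]].dropna()
    if len(sub) == 0:
        raise CbclError(f"all values missing for scale {scale!r}")
    if sub["diagnosis"].nunique() < 2:
        raise CbclError(
            f"single diagnosis class after missing-data exclusion on {scale!r}"
        )
    return sub


@dataclass
class CbclEvaluation:
    scale: str
    cutoff: float
    metrics: Metrics
    n_used: int
    n_missing: int

    def to_dict(self) -> dict:
        d = self.metrics.to_dict()
        d.update(scale=self.scale, cutoff=self.cutoff,
                 n_used=self.n_used, n_missing=self.n_missing)
        return d


def cbcl_evaluate(records: pd.DataFrame, scale: str,
                  cutoff: float = CLINICAL_CUTOFF) -> CbclEvaluation:
    """Accuracy/sensitivity/specificity of the T >= cutoff screen on one
    scale.  ``records`` needs a ``diagnosis`` column (0/1) plus one
    column per scale; missing T scores are excluded and counted."""
    sub = _complete_cases(records, scale)
    pred = cutoff_classify(sub[scale].to_numpy(), cutoff)
    # reuse the score-threshold machinery: scores are the predictions
    metrics = classification_metrics(pred.astype(float),
                                     sub["diagnosis"].to_numpy(), tau=0.5)
    return CbclEvaluation(
        scale=scale,
        cutoff=cutoff,
        metrics=metrics,
        n_used=len(sub),
        n_missing=len(records) - len(sub),
    )


def cbcl_auc(records: pd.DataFrame, scale: str) -> tuple[float, int]:
    """Threshold-free AUC of the continuous T score against diagnosis;
    returns (auc, n_used)."""
    sub = _complete_cases(records, scale)
    _, auc = roc_auc(sub[scale].to_numpy(), sub["diagnosis"].to_numpy())
    return auc, len(sub)
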