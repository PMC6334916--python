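"""Permutation test of the classifier's error rate against chance.

The cross-validated classifier produces a single observed error rate
(k incorrect out of n).  Its sampling uncertainty is approximated by a
beta distribution over error rates — Beta(k+1, n-k+1), the
Bayes-Laplace posterior under a uniform prior, which stays proper at
k = 0 (the raw Beta(k, n-k) shape is available by option) — from which
m rates are drawn.  The chance reference repeats the FULL
leave-one-subject-out pipeline (fold-internal standardization, feature
selection and logistic fit) for m uniform random permutations of the
diagnostic labels, recording each permuted error rate.  The two
m-vectors are then compared with a two-sided rank test: by default the
Wilcoxon signed-rank on index-paired differences (both sides are i.i.d.
draws, so the pairing is arbitrary but harmless), with the unpaired
Mann-Whitney U as an alternative.  The reported direction is the sign
of the median observed-minus-null difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import CvResult, loso_evaluate


class ChanceTestError(ValueError):
    pass


def sample_error_beta(
    n_incorrect: int,
    n_total: int,
    m: int = 100,
    seed: int | np.random.Generator | None = None,
    shape: str = "laplace",
) -> np.ndarray:
    """Draw ``m`` error rates from the beta approximation to the
    observed error distribution.

    ``shape="laplace"`` (default) uses Beta(k+1, n-k+1); ``shape="raw"``
    uses Beta(k, n-k) and requires 0 < k < n.
    """
    if not (0 <= n_incorrect <= n_total) or n_total <= 0:
        raise ChanceTestError(
            f"invalid counts: {n_incorrect} incorrect of {n_total}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if shape == "laplace":
        a, b = n_incorrect + 1, n_total - n_incorrect + 1
    elif shape == "raw":
        if n_incorrect in (0, n_total):
            raise ChanceTestError(
                "raw beta shape is degenerate at k=0 or k=n; use shape='laplace'"
            )
        a, b = n_incorrect, n_total - n_incorrect
    else:
        raise ChanceTestError(f"unknown beta shape {shape!r}")
    return rng.beta(a, b, size=m)


def permutation_null(
    X: pd.DataFrame,
    labels,
    m: int = 100,
    seed: int | np.random.Generator | None = None,
    k: int = 10,
    tau: float = 0.5,
    q: int = 1,
) -> np.ndarray:
    """Error rates of the full LOSO pipeline under ``m`` uniform label
    permutations (class balance preserved by construction)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = np.asarray(labels)
    out = np.empty(m)
    for j in range(m):
        yp = rng.permutation(y)
        out[j] = loso_evaluate(X, yp, k=k, tau=tau, q=q).error_rate
    return out


def compare_to_chance(
    observed_samples,
    null_samples,
    method: str = "wilcoxon",
) -> tuple[float, str]:
    """Two-sided p-value and direction for observed vs permuted error
    rates.  ``method`` is "wilcoxon" (paired signed-rank, default) or
    "mannwhitney" (unpaired U)."""
    obs = np.asarray(observed_samples, dtype=float)
    null = np.asarray(null_samples, dtype=float)
    if obs.size == 0 or null.size == 0:
        raise ChanceTestError("empty sample vector")
    if method == "wilcoxon":
        if obs.size != null.size:
            raise ChanceTestError("paired comparison needs equal-length samples")
        diffs = obs - null
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(obs, null, alternative="two-sided").pvalue)
    elif method == "mannwhitney":
        p = float(stats.mannwhitneyu(obs, null, alternative="two-sided").pvalue)
    else:
        raise ChanceTestError(f"unknown method {method!r}")

    med = float(np.median(obs) - np.median(null))
    direction = "below chance" if med < 0 else ("above chance" if med > 0 else "at chance")
    return p, direction


@dataclass
class ChanceTestResult:
    observed_error: float
    observed_samples: np.ndarray
    null_samples: np.ndarray
    p_value: float
    direction: str
    m: int
    seed: int | None
    method: str

    def to_dict(self) -> dict:
        return {
            "observed_error": self.observed_error,
            "null_median": float(np.median(self.null_samples)),
            "p_value": self.p_value,
            "direction": self.direction,
            "m": self.m,
            "seed": self.seed,
            "method": self.method,
        }


def run_chance_test(
    X: pd.DataFrame,
    labels,
    m: int = 100,
    seed: int | None = None,
    k: int = 10,
    tau: float = 0.5,
    q: int = 1,
    method: str = "wilcoxon",
    beta_shape: str = "laplace",
    cv_result: CvResult | None = None,
) -> ChanceTestResult:
    """Full chance test for one feature table: observed LOSO error →
    beta samples; label-permutation null; rank-test comparison.  All
    randomness flows from ``seed``."""
    rng = np.random.default_rng(seed)
    cv = cv_result if cv_result is not None else loso_evaluate(X, labels, k=k, tau=tau, q=q)
    obs = sample_error_beta(cv.n_incorrect, cv.n_subjects, m=m, seed=rng,
                            shape=beta_shape)
    null = permutation_null(X, labels, m=m, seed=rng, k=k, tau=tau, q=q)
    p, direction = compare_to_chance(obs, null, method=method)
    return ChanceTestResult(
        observed_error=cv.error_rate,
        observed_samples=obs,
        null_samples=null,
        p_value=p,
        direction=direction,
        m=m,
        seed=seed,
        method=method,
    )
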