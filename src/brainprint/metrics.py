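"""Accuracy and identifiability statistics plus significance procedures.

* identification accuracy — fraction of runs where the top-similarity
  source is the true individual (chance 1/K);
* rank accuracy — normalized mid-rank of the true match's similarity within
  a target's row (chance (K+1)/(2K));
* differential identifiability — 100 x (mean diagonal - mean off-diagonal)
  of the target x source similarity matrix (chance 0);
* permutation significance — null built by permuting the true identity
  labels of target individuals within each run;
* two-sided unpaired Student's t test for condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError
from .identify import IdentificationResult, SimilarityMatrix

__all__ = [
    "identification_accuracy",
    "rank_accuracy",
    "rank_accuracy_table",
    "differential_identifiability",
    "differential_identifiability_result",
    "chance_levels",
    "confusion_matrix",
    "permutation_pvalue",
    "PermutationTest",
    "unpaired_t_test",
    "ChanceLevels",
]


class ChanceLevels(NamedTuple):
    identification: float
    rank: float
    differential: float


def chance_levels(K: int) -> ChanceLevels:
    """Chance levels for K individuals: identification 1/K, rank accuracy
    (K+1)/(2K), differential identifiability 0."""
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    return ChanceLevels(1.0 / K, (K + 1) / (2.0 * K), 0.0)


def _se(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def identification_accuracy(result: IdentificationResult,
                            level: str = "pooled") -> pd.DataFrame:
    """Identification accuracy rows.

    ``level="individual"``: one row per individual, accuracy averaged over
    runs.  ``level="pooled"``: one row, averaged over individuals and runs.
    SEs are across the pooled correctness indicators.
    """
    correct = result.correct.astype(float)  # [R, K]
    base = {
        "feature": result.feature_kind,
        "source_session": result.config.get("source_session", ""),
        "target_session": result.config.get("target_session", ""),
    }
    if level == "individual":
        rows = [
            {**base, "individual": ind,
             "identification_accuracy": correct[:, i].mean(),
             "rank_accuracy": (result.ranks[:, i]
                               / result.n_individuals).mean(),
             "n_runs": result.n_runs, "se": _se(correct[:, i])}
            for i, ind in enumerate(result.target_ids)
        ]
        return pd.DataFrame(rows)
    if level == "pooled":
        return pd.DataFrame([{
            **base, "individual": "pooled",
            "identification_accuracy": correct.mean(),
            "rank_accuracy": (result.ranks / result.n_individuals).mean(),
            "n_runs": result.n_runs, "se": _se(correct)}])
    raise ValueError(f"level must be individual|pooled, got {level!r}")


def rank_accuracy(sim: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Per-individual rank accuracy of one similarity matrix.

    rank_i = mid-rank of values[i, i] within row i; rank accuracy =
    rank_i / K, in [1/K, 1].
    """
    values = sim.values if isinstance(sim, SimilarityMatrix) else np.asarray(sim)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("rank accuracy needs a square similarity matrix")
    k = values.shape[0]
    ranks = stats.rankdata(values, axis=1, method="average")
    return ranks[np.arange(k), np.arange(k)] / k


def rank_accuracy_table(result: IdentificationResult) -> pd.DataFrame:
    """Mean rank accuracy per individual across runs."""
    ra = result.ranks / result.n_individuals
    return pd.DataFrame({
        "individual": result.target_ids,
        "rank_accuracy": ra.mean(axis=0),
        "se": [_se(ra[:, i]) for i in range(result.n_individuals)],
        "n_runs": result.n_runs,
    })


def differential_identifiability(C: SimilarityMatrix | np.ndarray) -> float:
    """100 x (mean diagonal - mean off-diagonal) of a K x K similarity
    matrix; 0 when same- and different-individual similarities coincide."""
    values = C.values if isinstance(C, SimilarityMatrix) else np.asarray(C, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("differential identifiability needs a square matrix")
    k = values.shape[0]
    if k < 2:
        raise ValueError("need K >= 2")
    diag = np.trace(values) / k
    off = (values.sum() - np.trace(values)) / (k * (k - 1))
    return float(100.0 * (diag - off))


def differential_identifiability_result(
    result: IdentificationResult, per_run: bool = True,
) -> tuple[float, float]:
    """Differential identifiability of an identification experiment.

    Default: evaluate per run and average (returns mean, SE across runs).
    ``per_run=False`` evaluates the run-averaged similarity matrix instead
    (SE is then 0).
    """
    if per_run:
        vals = np.array([differential_identifiability(c)
                         for c in result.similarities])
        return float(vals.mean()), _se(vals)
    return differential_identifiability(result.similarities.mean(axis=0)), 0.0


def confusion_matrix(result: IdentificationResult) -> pd.DataFrame:
    """[K x K] assignment counts: entry (i, j) = runs in which target i was
    assigned source j.  Rows sum to R."""
    k = result.n_individuals
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        counts[i] = np.bincount(result.assignments[:, i], minlength=k)
    return pd.DataFrame(counts, index=result.target_ids,
                        columns=result.source_ids)


@dataclass
class PermutationTest:
    observed: float
    p_value: float
    B: int
    null_values: np.ndarray


def permutation_pvalue(result: IdentificationResult, B: int = 4999,
                       rng: np.random.Generator | int | None = None,
                       ) -> PermutationTest:
    """Permutation significance of the pooled identification accuracy.

    Null: within each run, permute the true identity labels of the target
    individuals and recompute pooled accuracy; p = (1 + #{null >= observed})
    / (1 + B).  With B = 4999 the smallest attainable p is 1/5000 = 0.0002.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    assign = result.assignments  # [R, K]
    r, k = assign.shape
    observed = float(result.correct.mean())
    # [B, R, K] random permutations: ranks of iid uniforms along last axis
    perms = np.argsort(rng.random((B, r, k)), axis=-1)
    null = (assign[None, :, :] == perms).mean(axis=(1, 2))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + B)
    return PermutationTest(observed=observed, p_value=float(p), B=B,
                           null_values=null)


def unpaired_t_test(a, b) -> tuple[float, float]:
    """Classical two-sample Student's t test (pooled variance, two-sided).

    Returns (t, p).  Raises on zero pooled variance (both samples constant),
    where the statistic is undefined.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs length >= 2")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        raise DegenerateDataError("zero pooled variance: t is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
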