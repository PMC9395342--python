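"""Within-session topomap classification baseline.

A topomap is the vector of all channel values at one time point.  The
baseline samples topomaps per individual, labels them with the identity,
and scores a 256-tree random forest under 10-fold cross-validation.  As in
the protocol it accompanies, train and test folds are z-scored by channel
separately and independently (a config flag restores the conventional
train-fitted scaling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochsTensor
from .errors import ValidationError

__all__ = [
    "TopomapSample",
    "sample_topomaps",
    "topomap_dataset",
    "rf_cv_accuracy",
    "RFBaselineResult",
]


@dataclass
class TopomapSample:
    """One [C] channel snapshot with its identity label and origin."""

    vector: np.ndarray
    label: str
    origin: tuple[int, int]  # (trial, time index)


def sample_topomaps(
    tensor: EpochsTensor, count: int, one_per_trial: bool = False,
    rng: np.random.Generator | int | None = None,
) -> list[TopomapSample]:
    """Sample ``count`` topomaps uniformly over (trial, time) pairs.

    With ``one_per_trial``, ``count`` distinct trials are drawn without
    replacement and one uniformly random time index is taken from each, so
    no two samples share a trial.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    t, n = tensor.n_times, tensor.n_trials
    if count < 1:
        raise ValueError("count must be >= 1")
    if one_per_trial:
        if count > n:
            raise ValueError(
                f"count={count} exceeds N={n} trials with one_per_trial")
        trials = rng.choice(n, size=count, replace=False)
        times = rng.integers(0, t, size=count)
    else:
        flat = rng.integers(0, t * n, size=count)
        trials, times = flat // t, flat % t
    return [
        TopomapSample(vector=tensor.data[:, ti, tr].copy(),
                      label=tensor.individual_id, origin=(int(tr), int(ti)))
        for tr, ti in zip(trials, times)
    ]


def topomap_dataset(
    blocks: Iterable[EpochsTensor], count: int, one_per_trial: bool = False,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack ``count`` topomaps per block into (X [n_samples, C], y)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    xs, ys = [], []
    for blk in blocks:
        samples = sample_topomaps(blk, count, one_per_trial, rng)
        xs.append(np.vstack([s.vector for s in samples]))
        ys.extend(s.label for s in samples)
    return np.vstack(xs), np.asarray(ys)


@dataclass
class RFBaselineResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    n_estimators: int
    folds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fold": np.arange(len(self.fold_accuracies)),
            "accuracy": self.fold_accuracies,
        })


def _zscore_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def rf_cv_accuracy(
    X: np.ndarray, y: np.ndarray, n_estimators: int = 256, folds: int = 10,
    rng: np.random.Generator | int | None = None,
    independent_zscore: bool = True, n_jobs: int = 1,
) -> RFBaselineResult:
    """Mean held-out accuracy of a random forest over stratified K folds.

    ``independent_zscore=True`` z-scores train and test folds by channel
    separately and independently (each with its own statistics);
    ``False`` applies train statistics to the test fold instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    if folds < 2 or folds > counts.min():
        raise ValueError(
            f"folds={folds} must be in [2, min class count={counts.min()}]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    seed = int(rng.integers(0, 2**31 - 1))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for fold_i, (train, test) in enumerate(skf.split(X, y)):
        xtr, xte = X[train], X[test]
        if independent_zscore:
            xtr, xte = _zscore_columns(xtr), _zscore_columns(xte)
        else:
            mu, sd = xtr.mean(axis=0), xtr.std(axis=0)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=seed + fold_i,
                                     n_jobs=n_jobs)
        clf.fit(xtr, y[train])
        accs.append(float(clf.score(xte, y[test])))
    accs = np.asarray(accs)
    return RFBaselineResult(fold_accuracies=accs,
                            mean_accuracy=float(accs.mean()),
                            n_estimators=n_estimators, folds=folds)
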