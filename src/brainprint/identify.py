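"""1-nearest-neighbor identification with correlation similarity.

Each target individual's feature vector is matched to the most similar
source feature ("labeling with replacement": targets are matched
independently, so several targets may receive the same source label).
Similarity is Pearson correlation.  The full protocol repeats the
sample-trials -> z-score -> featurize -> match cycle over R runs; when
source and target come from the same session, a fresh disjoint trial split
is drawn every run to prevent leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

from .epochs import EpochsTensor, SessionSet, split_within_session
from .errors import DegenerateDataError, ProtocolError
from .features import (BrainprintFeature, FEATURE_KINDS, featurize_block,
                       sample_trials, zscore_by_channel)

__all__ = [
    "SimilarityMatrix",
    "IdentificationResult",
    "similarity_matrix",
    "match_1nn",
    "run_identification",
    "CorrelationIdentifier",
]


@dataclass
class SimilarityMatrix:
    """Pearson similarities between K_target target and K_source source
    feature vectors; row i is target individual ``target_ids[i]``."""

    values: np.ndarray
    target_ids: list[str]
    source_ids: list[str]
    feature_kind: str = "sp"
    run_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("similarity values must be 2-D")
        if self.values.shape != (len(self.target_ids), len(self.source_ids)):
            raise ValueError("similarity shape does not match id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity values must be finite")


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross Pearson correlation of two [K, d] matrices."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    asd = a.std(axis=1)
    bsd = b.std(axis=1)
    for name, sd in (("target", asd), ("source", bsd)):
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            raise DegenerateDataError(
                f"zero-variance {name} feature vector at index {bad[0]}"
            )
    az = (a - a.mean(axis=1, keepdims=True)) / asd[:, None]
    bz = (b - b.mean(axis=1, keepdims=True)) / bsd[:, None]
    return np.clip(az @ bz.T / a.shape[1], -1.0, 1.0)


def _vectors(feats: Sequence) -> np.ndarray:
    rows = [f.vector if isinstance(f, BrainprintFeature) else np.asarray(f)
            for f in feats]
    return np.vstack(rows)


def similarity_matrix(
    target_feats: Sequence, source_feats: Sequence,
    target_ids: Sequence[str] | None = None,
    source_ids: Sequence[str] | None = None,
    feature_kind: str = "sp", run_index: int = 0,
) -> SimilarityMatrix:
    """Pearson correlation between every target and source feature vector."""
    tv = _vectors(target_feats)
    sv = _vectors(source_feats)
    if tv.shape[1] != sv.shape[1]:
        raise ProtocolError(
            f"feature lengths differ: target {tv.shape[1]}, source {sv.shape[1]}"
        )
    if sv.shape[0] < 2:
        raise ProtocolError("need at least K=2 source individuals")
    tids = list(target_ids) if target_ids is not None \
        else [str(i) for i in range(tv.shape[0])]
    sids = list(source_ids) if source_ids is not None \
        else [str(i) for i in range(sv.shape[0])]
    return SimilarityMatrix(values=_pearson_rows(tv, sv), target_ids=tids,
                            source_ids=sids, feature_kind=feature_kind,
                            run_index=run_index)


def match_1nn(sim: SimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Assign each target row to its argmax source column (with replacement).

    Returns ``(assignments, tie_flags)``: exact ties resolve to the lowest
    source index and are flagged.
    """
    v = sim.values
    assignments = v.argmax(axis=1)
    row_max = v[np.arange(v.shape[0]), assignments]
    tie_flags = (v == row_max[:, None]).sum(axis=1) > 1
    return assignments, tie_flags


@dataclass
class IdentificationResult:
    """All per-run, per-individual outcomes of an identification experiment.

    ``similarities`` is [R, K, K] with row order = ``target_ids`` and column
    order = ``source_ids``; the two id lists name the same individuals in
    the same order, so the diagonal is the true match.  ``ranks`` are
    mid-ranks of the true-match similarity within each row (rank K = most
    similar).
    """

    feature_kind: str
    target_ids: list[str]
    source_ids: list[str]
    similarities: np.ndarray   # [R, K, K]
    assignments: np.ndarray    # [R, K] int
    correct: np.ndarray        # [R, K] bool
    ranks: np.ndarray          # [R, K] float
    tie_flags: np.ndarray      # [R, K] bool
    config: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.assignments.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format run-level results (one row per run x individual)."""
        r, k = self.assignments.shape
        runs, inds = np.meshgrid(np.arange(r), np.arange(k), indexing="ij")
        return pd.DataFrame({
            "run": runs.ravel(),
            "individual": np.array(self.target_ids)[inds.ravel()],
            "feature": self.feature_kind,
            "source_session": self.config.get("source_session", ""),
            "target_session": self.config.get("target_session", ""),
            "assigned": np.array(self.source_ids)[self.assignments.ravel()],
            "correct": self.correct.ravel(),
            "rank": self.ranks.ravel(),
            "tie_flag": self.tie_flags.ravel(),
        })


def _mid_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-rank of the diagonal entry within each row of [R, K, K]."""
    r, k, _ = values.shape
    flat = values.reshape(r * k, k)
    ranks = rankdata(flat, axis=1, method="average")
    diag = np.tile(np.arange(k), r)
    return ranks[np.arange(r * k), diag].reshape(r, k)


def _result_from_sims(sims: np.ndarray, target_ids, source_ids,
                      feature_kind, config) -> IdentificationResult:
    assignments = sims.argmax(axis=2)
    row_max = np.take_along_axis(sims, assignments[..., None], axis=2)
    tie_flags = (sims == row_max).sum(axis=2) > 1
    correct = assignments == np.arange(sims.shape[1])[None, :]
    return IdentificationResult(
        feature_kind=feature_kind, target_ids=list(target_ids),
        source_ids=list(source_ids), similarities=sims,
        assignments=assignments, correct=correct,
        ranks=_mid_ranks(sims), tie_flags=tie_flags, config=config,
    )


def iter_run_features(
    source: SessionSet, target: SessionSet, feature_kind: str,
    n: int, R: int, rng: np.random.Generator,
    split_fraction: float = 0.5, resplit_per_run: bool = True,
    vectorize: str = "upper", fq_kwargs: dict | None = None,
):
    """Yield per-run aligned (target_vectors, source_vectors) [K, d] arrays.

    Implements the per-run protocol: same-session pairs draw a fresh
    disjoint split each run, then each side is z-scored, ``n`` trials are
    sampled, and the block is featurized.  Row order is
    :func:`protocol_individuals` (sorted target ids) on both sides, so the
    diagonal of any derived similarity matrix is the true match.
    """
    fq_kwargs = fq_kwargs or {}
    src_blocks = source.blocks_by_individual()
    tgt_blocks = target.blocks_by_individual()
    individuals = sorted(tgt_blocks)
    missing = [i for i in individuals if i not in src_blocks]
    if missing:
        raise ProtocolError(f"individuals missing from source: {missing}")
    if len(individuals) < 2:
        raise ProtocolError("need at least 2 individuals")

    def _same_recording(a: EpochsTensor, b: EpochsTensor) -> bool:
        # the leakage guard (per-run disjoint splits) applies when source
        # and target are the same recording, not merely same-named sessions
        # (e.g. two modalities may both label their visit "ses-00")
        if a is b:
            return True
        return (a.session_id == b.session_id
                and a.data.shape == b.data.shape
                and np.array_equal(a.data, b.data))

    same_session = {
        ind: _same_recording(src_blocks[ind], tgt_blocks[ind])
        for ind in individuals
    }

    def _feat(tensor: EpochsTensor) -> np.ndarray:
        zs = zscore_by_channel(tensor)
        sampled = sample_trials(zs, n, rng)
        return featurize_block(sampled, feature_kind, vectorize=vectorize,
                               **fq_kwargs).vector

    # validate n feasibility up front
    for ind in individuals:
        if same_session[ind]:
            n_tgt = int(round(src_blocks[ind].n_trials * split_fraction))
            if n > min(n_tgt, src_blocks[ind].n_trials - n_tgt):
                raise ValueError(
                    f"n={n} infeasible for within-session split of "
                    f"{src_blocks[ind].n_trials} trials"
                )
        else:
            if n > src_blocks[ind].n_trials or n > tgt_blocks[ind].n_trials:
                raise ValueError(
                    f"n={n} exceeds available trials for {ind!r}")

    fixed_splits = {}
    if not resplit_per_run:
        for ind in individuals:
            if same_session[ind]:
                fixed_splits[ind] = split_within_session(
                    src_blocks[ind], split_fraction, rng)

    for r in range(R):
        tgt_vecs, src_vecs = [], []
        for ind in individuals:
            if same_session[ind]:
                if resplit_per_run:
                    src_half, tgt_half = split_within_session(
                        src_blocks[ind], split_fraction, rng)
                else:
                    src_half, tgt_half = fixed_splits[ind]
            else:
                src_half, tgt_half = src_blocks[ind], tgt_blocks[ind]
            src_vecs.append(_feat(src_half))
            tgt_vecs.append(_feat(tgt_half))
        yield np.vstack(tgt_vecs), np.vstack(src_vecs)


def protocol_individuals(source: SessionSet, target: SessionSet) -> list[str]:
    """The fixed individual ordering used by the protocol (sorted target ids)."""
    return sorted(target.blocks_by_individual())


def run_identification(
    source: SessionSet, target: SessionSet, feature_kind: str,
    n: int, R: int = 100, rng: np.random.Generator | int | None = None,
    split_fraction: float = 0.5, resplit_per_run: bool = True,
    vectorize: str = "upper", fq_kwargs: dict | None = None,
) -> IdentificationResult:
    """Run the full R-run 1NN identification protocol.

    Per run: sample ``n`` trials per block on each side (after per-side
    z-scoring by channel), featurize with ``feature_kind``, build the
    Pearson similarity matrix and match with replacement.  When a pair of
    blocks shares a session, a fresh disjoint split is drawn each run
    (``resplit_per_run=False`` fixes one split for all runs).
    """
    if feature_kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    individuals = protocol_individuals(source, target)
    k = len(individuals)
    sims = np.empty((R, k, k))
    for r, (tv, sv) in enumerate(iter_run_features(
            source, target, feature_kind, n, R, rng,
            split_fraction=split_fraction, resplit_per_run=resplit_per_run,
            vectorize=vectorize, fq_kwargs=fq_kwargs)):
        sims[r] = _pearson_rows(tv, sv)

    src_blocks = source.blocks_by_individual()
    tgt_blocks = target.blocks_by_individual()
    config = {
        "feature": feature_kind, "n": n, "R": R,
        "split_fraction": split_fraction,
        "resplit_per_run": resplit_per_run,
        "source_session": ",".join(sorted({b.session_id
                                           for b in src_blocks.values()})),
        "target_session": ",".join(sorted({b.session_id
                                           for b in tgt_blocks.values()})),
    }
    return _result_from_sims(sims, individuals, individuals, feature_kind,
                             config)


class CorrelationIdentifier(ClassifierMixin, BaseEstimator):
    """1-nearest-neighbor classifier with Pearson-correlation similarity.

    ``fit`` stores one labeled reference (source) feature vector per class;
    ``predict`` assigns each query (target) vector to the class of its most
    similar reference, independently per query ("with replacement").

    Attributes
    ----------
    classes_ : ndarray of unique labels (sorted)
    source_vectors_ : ndarray [n_classes, d], row i for ``classes_[i]``
    """

    def fit(self, X, y) -> "CorrelationIdentifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be [n_samples, d] aligned with y")
        classes, inverse = np.unique(y, return_inverse=True)
        if classes.shape[0] != y.shape[0]:
            raise ValueError(
                "CorrelationIdentifier expects exactly one reference vector "
                "per class"
            )
        order = np.argsort(inverse)
        self.classes_ = classes
        self.source_vectors_ = X[order]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Similarity of each query row to every fitted class reference."""
        X = np.asarray(X, dtype=float)
        return _pearson_rows(X, self.source_vectors_)

    def predict(self, X) -> np.ndarray:
        sim = self.decision_function(X)
        return self.classes_[sim.argmax(axis=1)]
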