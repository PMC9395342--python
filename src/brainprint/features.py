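"""The three brainprint features and their trial-sampling conventions.

Given an epoch block ``X`` of shape [C, T, n]:

* **sp** — spatial correlation: the [C x C] Pearson correlation between
  channels, computed over the T*n concatenated time-trial samples;
* **tp** — temporal correlation: the [T x T] Pearson correlation between
  time points, computed over the C*n concatenated channel-trial samples;
* **fq** — frequency: the mean Tukey-tapered power spectrum over channels,
  trials (and Welch segments when trials are longer than the window),
  a vector of ``window_len // 2 + 1`` bins.

Similarity downstream is Pearson correlation between vectorized features;
for sp/tp the default vectorization is the upper triangle excluding the
(identically 1) diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from sklearn.base import BaseEstimator, TransformerMixin

from .epochs import EpochsTensor
from .errors import DegenerateDataError

__all__ = [
    "BrainprintFeature",
    "zscore_by_channel",
    "sample_trials",
    "compute_sp",
    "compute_tp",
    "compute_fq",
    "featurize_block",
    "BrainprintExtractor",
    "FEATURE_KINDS",
]

FEATURE_KINDS = ("sp", "tp", "fq")
_ZVAR_TOL = 0.0  # exact zero variance is degenerate


@dataclass
class BrainprintFeature:
    """One featurized sample.

    ``payload`` is the interpretable form (correlation matrix or power
    vector); ``vector`` is the flattened form used for similarity.
    """

    kind: str
    payload: np.ndarray
    vector: np.ndarray
    n_trials_used: int
    freq_bins_hz: np.ndarray | None = None   # fq only
    channel_names: list[str] | None = None   # sp only (for sub-features)
    sfreq: float | None = None


def zscore_by_channel(tensor: EpochsTensor) -> EpochsTensor:
    """Standardize each channel to mean 0, SD 1 over all T*N samples.

    Applied to source and target sets separately by the identification
    protocol.  A constant channel is degenerate and raises.
    """
    flat = tensor.data.reshape(tensor.n_channels, -1)
    mu = flat.mean(axis=1)
    sd = flat.std(axis=1)
    bad = np.nonzero(sd <= _ZVAR_TOL)[0]
    if bad.size:
        raise DegenerateDataError(
            f"zero-variance channel {bad[0]} ({tensor.channel_names[bad[0]]!r})"
        )
    data = (tensor.data - mu[:, None, None]) / sd[:, None, None]
    return replace(tensor, data=data)


def sample_trials(tensor: EpochsTensor, n: int,
                  rng: np.random.Generator) -> EpochsTensor:
    """Draw ``n`` distinct trials uniformly without replacement."""
    if not 1 <= n <= tensor.n_trials:
        raise ValueError(
            f"n must be in [1, {tensor.n_trials}], got {n}"
        )
    idx = rng.choice(tensor.n_trials, size=n, replace=False)
    return tensor.select_trials(idx)


def _corr(rows: np.ndarray, what: str, names=None) -> np.ndarray:
    """Pearson correlation between rows; degenerate rows raise."""
    sd = rows.std(axis=1)
    bad = np.nonzero(sd <= _ZVAR_TOL)[0]
    if bad.size:
        label = f" ({names[bad[0]]!r})" if names is not None else ""
        raise DegenerateDataError(f"constant {what} {bad[0]}{label}")
    c = np.corrcoef(rows)
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def _vectorize_square(payload: np.ndarray, vectorize: str) -> np.ndarray:
    if vectorize == "upper":
        iu = np.triu_indices(payload.shape[0], k=1)
        return payload[iu]
    if vectorize == "full":
        return payload.ravel()
    raise ValueError(f"vectorize must be 'upper' or 'full', got {vectorize!r}")


def compute_sp(tensor: EpochsTensor, vectorize: str = "upper") -> BrainprintFeature:
    """Spatial correlation feature: [C x C] Pearson correlation between
    channels over the concatenated time-trial axis."""
    rows = tensor.data.reshape(tensor.n_channels, -1)
    payload = _corr(rows, "channel", tensor.channel_names)
    return BrainprintFeature(
        kind="sp", payload=payload,
        vector=_vectorize_square(payload, vectorize),
        n_trials_used=tensor.n_trials,
        channel_names=list(tensor.channel_names),
        sfreq=tensor.sfreq,
    )


def compute_tp(tensor: EpochsTensor, vectorize: str = "upper") -> BrainprintFeature:
    """Temporal correlation feature: [T x T] Pearson correlation between
    time points over the concatenated channel-trial axis."""
    rows = np.moveaxis(tensor.data, 1, 0).reshape(tensor.n_times, -1)
    payload = _corr(rows, "time point")
    return BrainprintFeature(
        kind="tp", payload=payload,
        vector=_vectorize_square(payload, vectorize),
        n_trials_used=tensor.n_trials,
        sfreq=tensor.sfreq,
    )


def compute_fq(
    tensor: EpochsTensor,
    window_len: int | None = None,
    tukey_alpha: float = 0.25,
    overlap: float = 0.5,
) -> BrainprintFeature:
    """Frequency feature: power spectrum per channel and trial with a Tukey
    taper (shape ``tukey_alpha``) over segments of ``window_len`` samples,
    averaged over channels, trials and segments.

    Trials longer than the window are tiled Welch-style with the stated
    fractional overlap.  The payload has ``window_len // 2 + 1`` bins at
    spacing ``sfreq / window_len`` Hz.  ``window_len=None`` (default)
    resolves to ``min(100, T)``; an explicitly configured window longer
    than the trial is an error.
    """
    if window_len is None:
        window_len = min(100, tensor.n_times)
    if tensor.n_times < window_len:
        raise ValueError(
            f"T={tensor.n_times} shorter than window_len={window_len}"
        )
    x = np.moveaxis(tensor.data, 1, 2)  # [C, N, T]; time last
    freqs, pxx = _signal.welch(
        x, fs=tensor.sfreq, window=("tukey", tukey_alpha),
        nperseg=window_len, noverlap=int(round(overlap * window_len)),
        detrend=False, scaling="density", axis=-1,
    )
    payload = pxx.mean(axis=(0, 1))
    return BrainprintFeature(
        kind="fq", payload=payload, vector=payload.copy(),
        n_trials_used=tensor.n_trials, freq_bins_hz=freqs,
        sfreq=tensor.sfreq,
    )


def featurize_block(tensor: EpochsTensor, kind: str,
                    vectorize: str = "upper", **fq_kwargs) -> BrainprintFeature:
    """Dispatch to the named feature computation."""
    if kind == "sp":
        return compute_sp(tensor, vectorize=vectorize)
    if kind == "tp":
        return compute_tp(tensor, vectorize=vectorize)
    if kind == "fq":
        return compute_fq(tensor, **fq_kwargs)
    raise ValueError(f"unknown feature kind {kind!r}; expected one of {FEATURE_KINDS}")


class BrainprintExtractor(TransformerMixin, BaseEstimator):
    """Transform epoch blocks into brainprint feature vectors.

    A scikit-learn transformer over a sequence of :class:`EpochsTensor`
    blocks (or raw [C, T, N] arrays); ``transform`` returns one feature
    vector per block, ready for :class:`~brainprint.identify.CorrelationIdentifier`
    or any downstream sklearn estimator.

    Parameters
    ----------
    kind : {"sp", "tp", "fq"}
    n_trials : int or None
        If set, feature computation uses this many trials sampled uniformly
        without replacement (after z-scoring, matching the protocol default).
    zscore : bool
        Z-score each block by channel before featurizing.
    vectorize : {"upper", "full"}
        Flattening of the sp/tp correlation matrices.
    window_len, tukey_alpha, overlap :
        fq spectral parameters (ignored for sp/tp).
    random_state : int, Generator or None
        Seeds the trial sampling.
    """

    def __init__(self, kind: str = "sp", n_trials: int | None = None,
                 zscore: bool = True, vectorize: str = "upper",
                 window_len: int | None = None, tukey_alpha: float = 0.25,
                 overlap: float = 0.5, random_state=None):
        self.kind = kind
        self.n_trials = n_trials
        self.zscore = zscore
        self.vectorize = vectorize
        self.window_len = window_len
        self.tukey_alpha = tukey_alpha
        self.overlap = overlap
        self.random_state = random_state

    def _as_tensor(self, block) -> EpochsTensor:
        if isinstance(block, EpochsTensor):
            return block
        # raw [C, T, N] array: nominal sampling rate 2*T Hz (a 0.5 s trial)
        arr = np.asarray(block, dtype=float)
        return EpochsTensor(
            data=arr, sfreq=float(2 * arr.shape[1]),
            channel_names=[f"ch{i}" for i in range(arr.shape[0])],
            individual_id="anon", session_id="anon",
        )

    def _featurize(self, block, rng) -> BrainprintFeature:
        tensor = self._as_tensor(block)
        if self.zscore:
            tensor = zscore_by_channel(tensor)
        if self.n_trials is not None:
            tensor = sample_trials(tensor, self.n_trials, rng)
        if self.kind == "fq":
            return compute_fq(tensor, window_len=self.window_len,
                              tukey_alpha=self.tukey_alpha,
                              overlap=self.overlap)
        return featurize_block(tensor, self.kind, vectorize=self.vectorize)

    def fit(self, X: Sequence, y=None) -> "BrainprintExtractor":
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        first = self._as_tensor(X[0])
        self.n_channels_ = first.n_channels
        self.n_times_ = first.n_times
        if self.kind == "fq":
            wl = self.window_len if self.window_len is not None \
                else min(100, first.n_times)
            self.freq_bins_hz_ = np.fft.rfftfreq(wl, d=1.0 / first.sfreq)
        return self

    def transform(self, X: Sequence) -> np.ndarray:
        rng = np.random.default_rng(self.random_state) \
            if not isinstance(self.random_state, np.random.Generator) \
            else self.random_state
        feats = [self._featurize(b, rng) for b in X]
        return np.vstack([f.vector for f in feats])
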