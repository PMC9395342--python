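"""Epoched sensor-data model and I/O.

The canonical in-memory container is :class:`EpochsTensor`, a single
individual x session block of epoched data shaped ``[C channels, T time
points, N trials]`` with sampling rate and identity metadata.  The canonical
on-disk format is a small HDF5 layout (see :func:`write_epochs`); standard
FIF epoch files are supported as an import adapter via :mod:`mne`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import h5py
from scipy import signal

from .errors import ProtocolError, SchemaError, ValidationError

MODALITIES = ("MEG", "EEG", "SYNTH")

__all__ = [
    "EpochsTensor",
    "SessionSet",
    "read_epochs",
    "write_epochs",
    "downsample",
    "split_within_session",
    "pseudo_epochs",
    "to_mne_epochs",
    "from_mne_epochs",
    "write_fif",
]


@dataclass
class EpochsTensor:
    """One individual x session block of epoched sensor data.

    Parameters
    ----------
    data : ndarray, shape (C, T, N)
        Sensor time series; C channels, T time points per trial, N trials.
        Units are arbitrary and never rescaled by I/O.
    sfreq : float
        Sampling rate in Hz.
    channel_names : list of str
        C unique channel names.
    individual_id, session_id : str
        Identity labels used by the identification protocol.
    modality : {"MEG", "EEG", "SYNTH"}
    time_zero_index : int
        Sample index of stimulus onset within a trial (0 for onset-locked).
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    individual_id: str
    session_id: str
    modality: str = "SYNTH"
    time_zero_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be [C, T, N]; got shape {self.data.shape}"
            )
        c, t, n = self.data.shape
        if c < 2 or t < 2 or n < 1:
            raise ValidationError(
                f"need C >= 2, T >= 2, N >= 1; got C={c}, T={t}, N={n}"
            )
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))
            ch, tp, tr = bad[0]
            raise ValidationError(
                f"non-finite value at channel {ch} ({self.channel_names[ch]!r}), "
                f"time {tp}, trial {tr} ({len(bad)} offending entries total)"
            )
        self.channel_names = [str(x) for x in self.channel_names]
        if len(self.channel_names) != c:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if len(set(self.channel_names)) != c:
            raise ValidationError("channel names are not unique")
        if not self.sfreq > 0:
            raise ValidationError(f"sfreq must be > 0, got {self.sfreq}")
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )
        self.time_zero_index = int(self.time_zero_index)
        if not 0 <= self.time_zero_index < t:
            raise ValidationError(
                f"time_zero_index {self.time_zero_index} outside [0, {t})"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def select_trials(self, indices: np.ndarray) -> "EpochsTensor":
        """Return a copy restricted to the given trial indices (in order)."""
        idx = np.asarray(indices, dtype=int)
        return replace(self, data=self.data[:, :, idx].copy())

    def times(self) -> np.ndarray:
        """Time axis in seconds relative to stimulus onset."""
        return (np.arange(self.n_times) - self.time_zero_index) / self.sfreq


@dataclass
class SessionSet:
    """A role-labeled collection of epoch blocks keyed by (individual, session).

    ``role`` distinguishes the labeled reference set ("source") from the
    query set ("target") in the identification protocol.
    """

    blocks: dict[tuple[str, str], EpochsTensor] = field(default_factory=dict)
    role: str = "source"

    def __post_init__(self) -> None:
        if self.role not in ("source", "target"):
            raise ValidationError(f"role must be source|target, got {self.role!r}")
        for (ind, ses), blk in self.blocks.items():
            if blk.individual_id != ind or blk.session_id != ses:
                raise ProtocolError(
                    f"block keyed {(ind, ses)} carries ids "
                    f"({blk.individual_id!r}, {blk.session_id!r})"
                )

    @property
    def individuals(self) -> list[str]:
        return sorted({ind for ind, _ in self.blocks})

    @property
    def sessions(self) -> list[str]:
        return sorted({ses for _, ses in self.blocks})

    def blocks_by_individual(self) -> dict[str, EpochsTensor]:
        """Map individual -> unique block; error if an individual has several."""
        out: dict[str, EpochsTensor] = {}
        for (ind, _), blk in sorted(self.blocks.items()):
            if ind in out:
                raise ProtocolError(
                    f"individual {ind!r} has multiple blocks in this set"
                )
            out[ind] = blk
        return out

    def check_consistent(self) -> None:
        shapes = {(b.n_channels, b.n_times) for b in self.blocks.values()}
        if len(shapes) > 1:
            raise ProtocolError(f"blocks disagree on (C, T): {sorted(shapes)}")


# ---------------------------------------------------------------------------
# HDF5 container + FIF adapter

_REQUIRED_ATTRS = ("sfreq", "individual_id", "session_id", "modality",
                   "time_zero_index")


def write_epochs(tensor: EpochsTensor, path: str | Path) -> Path:
    """Write an :class:`EpochsTensor` to the canonical HDF5 layout.

    Layout: root attributes ``sfreq``, ``individual_id``, ``session_id``,
    ``modality``, ``time_zero_index``; dataset ``/data`` float64 [C, T, N];
    dataset ``/channel_names`` UTF-8 strings [C].
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sfreq"] = float(tensor.sfreq)
        f.attrs["individual_id"] = tensor.individual_id
        f.attrs["session_id"] = tensor.session_id
        f.attrs["modality"] = tensor.modality
        f.attrs["time_zero_index"] = int(tensor.time_zero_index)
        f.create_dataset("data", data=tensor.data.astype(np.float64),
                         track_times=False)
        f.create_dataset(
            "channel_names",
            data=np.array(tensor.channel_names,
                          dtype=h5py.string_dtype("utf-8")),
            track_times=False,
        )
    return path


def _read_hdf5(path: Path) -> EpochsTensor:
    with h5py.File(path, "r") as f:
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise SchemaError(f"{path}: missing required attribute {attr!r}")
        for dset in ("data", "channel_names"):
            if dset not in f:
                raise SchemaError(f"{path}: missing required dataset /{dset}")
        data = np.asarray(f["data"], dtype=np.float64)
        names = [x.decode() if isinstance(x, bytes) else str(x)
                 for x in f["channel_names"][()]]
        return EpochsTensor(
            data=data,
            sfreq=float(f.attrs["sfreq"]),
            channel_names=names,
            individual_id=str(f.attrs["individual_id"]),
            session_id=str(f.attrs["session_id"]),
            modality=str(f.attrs["modality"]),
            time_zero_index=int(f.attrs["time_zero_index"]),
        )


def to_mne_epochs(tensor: EpochsTensor):
    """Convert to :class:`mne.EpochsArray` (for FIF export / MNE interop)."""
    import mne

    ch_type = "eeg" if tensor.modality == "EEG" else "mag"
    info = mne.create_info(tensor.channel_names, tensor.sfreq,
                           ch_types=ch_type)
    # mne expects [N, C, T]
    data = np.moveaxis(tensor.data, 2, 0)
    tmin = -tensor.time_zero_index / tensor.sfreq
    return mne.EpochsArray(data, info, tmin=tmin, verbose="error")


def from_mne_epochs(epochs, individual_id: str = "unknown",
                    session_id: str = "unknown") -> EpochsTensor:
    """Build an :class:`EpochsTensor` from an MNE epochs object.

    Channel order is preserved and units are untouched.  Modality is EEG if
    every channel is an EEG channel, MEG otherwise.
    """
    data = np.moveaxis(epochs.get_data(copy=True), 0, 2)  # [C, T, N]
    types = epochs.get_channel_types()
    modality = "EEG" if types and all(t == "eeg" for t in types) else "MEG"
    tzero = int(round(-epochs.tmin * epochs.info["sfreq"]))
    return EpochsTensor(
        data=data,
        sfreq=float(epochs.info["sfreq"]),
        channel_names=list(epochs.ch_names),
        individual_id=individual_id,
        session_id=session_id,
        modality=modality,
        time_zero_index=max(tzero, 0),
    )


def write_fif(tensor: EpochsTensor, path: str | Path) -> Path:
    """Export to a FIF epochs file (``*-epo.fif``) at double precision."""
    path = Path(path)
    to_mne_epochs(tensor).save(path, overwrite=True, fmt="double",
                               verbose="error")
    return path


def read_epochs(path: str | Path, format: str | None = None,
                individual_id: str = "unknown",
                session_id: str = "unknown") -> EpochsTensor:
    """Read epochs from HDF5 (canonical) or a FIF epoch file.

    ``format`` is inferred from the suffix when omitted (``.fif`` -> fif,
    otherwise hdf5).  FIF files carry no individual/session labels, so those
    must be supplied by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "fif" if path.suffix == ".fif" else "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "fif":
        import mne

        epochs = mne.read_epochs(path, preload=True, verbose="error")
        return from_mne_epochs(epochs, individual_id, session_id)
    raise ValueError(f"unsupported format {format!r}")


# ---------------------------------------------------------------------------
# Preprocessing kept in scope: resampling, splitting, pseudo-trials


def downsample(tensor: EpochsTensor, target_sfreq: float) -> EpochsTensor:
    """Anti-aliased downsampling of the time axis to ``target_sfreq``.

    Polyphase FIR resampling (`scipy.signal.resample_poly`) applies a
    linear-phase anti-alias low-pass with compensated delay, so evoked
    latencies are not shifted.  The new trial length is
    ``round(T * target_sfreq / sfreq)`` for rational rate ratios.
    """
    if not target_sfreq < tensor.sfreq:
        raise ValueError(
            f"target_sfreq ({target_sfreq}) must be < sfreq ({tensor.sfreq})"
        )
    ratio = Fraction(float(target_sfreq) / float(tensor.sfreq)).limit_denominator(1000)
    if abs(float(ratio) - target_sfreq / tensor.sfreq) > 1e-9:
        raise ValueError(
            "sfreq ratio is not rational within tolerance 1e-9; "
            f"got {target_sfreq}/{tensor.sfreq}"
        )
    out = signal.resample_poly(tensor.data, ratio.numerator, ratio.denominator,
                               axis=1)
    new_tzero = int(round(tensor.time_zero_index * float(ratio)))
    return replace(tensor, data=out, sfreq=float(target_sfreq),
                   time_zero_index=min(new_tzero, out.shape[1] - 1))


def split_within_session(
    tensor: EpochsTensor, target_fraction: float,
    rng: np.random.Generator,
) -> tuple[EpochsTensor, EpochsTensor]:
    """Randomly split trials into disjoint, exhaustive (source, target) sets.

    ``target_fraction`` of the N trials (rounded) go to the target set; the
    remainder to the source set.  The assignment is a pure function of the
    generator state.
    """
    n = tensor.n_trials
    if not 0.0 < target_fraction < 1.0:
        raise ValueError(f"target_fraction must be in (0, 1), got {target_fraction}")
    n_target = int(round(n * target_fraction))
    if n_target == 0 or n_target == n:
        raise ValueError(
            f"target_fraction {target_fraction} leaves an empty side for N={n}"
        )
    perm = rng.permutation(n)
    target_idx = np.sort(perm[:n_target])
    source_idx = np.sort(perm[n_target:])
    return tensor.select_trials(source_idx), tensor.select_trials(target_idx)


def pseudo_epochs(
    data: np.ndarray, trial_len: int, sfreq: float,
    channel_names: Iterable[str], **meta,
) -> EpochsTensor:
    """Reshape a continuous [C, T_total] recording into fixed-length
    pseudo-trials of ``trial_len`` samples (the resting-state treatment).

    Trailing samples that do not fill a whole trial are dropped.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValidationError("continuous data must be [C, T_total]")
    if trial_len < 2:
        raise ValueError("trial_len must be >= 2")
    c, total = data.shape
    n = total // trial_len
    if n < 1:
        raise ValueError(
            f"recording of {total} samples shorter than one trial ({trial_len})"
        )
    trimmed = data[:, : n * trial_len].reshape(c, n, trial_len)
    arranged = np.moveaxis(trimmed, 1, 2)  # [C, trial_len, N]
    meta.setdefault("individual_id", "unknown")
    meta.setdefault("session_id", "unknown")
    return EpochsTensor(data=arranged, sfreq=sfreq,
                        channel_names=list(channel_names), **meta)
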