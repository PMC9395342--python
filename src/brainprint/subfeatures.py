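"""Decompose brainprints into components and attribute identifiability.

* sp — channels are partitioned into 8 named sensor groups (left/right x
  frontal/temporal/parietal/occipital); each component is one group-pair
  block of the spatial correlation matrix;
* tp — time points are divided into consecutive equal segments (default
  10); each component is one segment-pair block of the temporal
  correlation matrix;
* fq — each component is the slice of the power vector covering a 10 Hz
  window [f, f+10] with f on the bin grid, or a canonical band.

:func:`subfeature_accuracy_map` reruns the full identification protocol
with similarity computed on each component alone, yielding an accuracy per
grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ProtocolError, ValidationError
from .features import BrainprintFeature
from .identify import (SessionSet, _pearson_rows, _result_from_sims,
                       iter_run_features, protocol_individuals)

__all__ = [
    "SENSOR_GROUPS",
    "CANONICAL_BANDS",
    "SensorGroupLayout",
    "default_layout",
    "layout_from_positions",
    "sp_block",
    "tp_block",
    "fq_window",
    "fq_band",
    "subfeature_accuracy_map",
]

SENSOR_GROUPS = ("LF", "RF", "LT", "RT", "LP", "RP", "LO", "RO")

# canonical frequency bands, Hz (inclusive start, exclusive stop)
CANONICAL_BANDS = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}


@dataclass
class SensorGroupLayout:
    """Mapping channel name -> one of the 8 sensor groups."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.mapping.values() if g not in SENSOR_GROUPS}
        if bad:
            raise ValidationError(f"unknown sensor groups: {sorted(bad)}")
        present = set(self.mapping.values())
        missing = [g for g in SENSOR_GROUPS if g not in present]
        if missing:
            raise ValidationError(f"empty sensor groups: {missing}")

    def indices(self, group: str, channel_names: list[str]) -> np.ndarray:
        """Positions of the group's channels within ``channel_names``."""
        if group not in SENSOR_GROUPS:
            raise ValueError(f"unknown group {group!r}; expected {SENSOR_GROUPS}")
        unmapped = [c for c in channel_names if c not in self.mapping]
        if unmapped:
            raise ValidationError(f"channels not in layout: {unmapped[:5]}")
        idx = [i for i, c in enumerate(channel_names)
               if self.mapping[c] == group]
        return np.asarray(idx, dtype=int)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame({"channel_name": list(self.mapping),
                      "group": list(self.mapping.values())}
                     ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorGroupLayout":
        df = pd.read_csv(path)
        for col in ("channel_name", "group"):
            if col not in df.columns:
                raise ValidationError(f"layout file missing column {col!r}")
        return cls(dict(zip(df["channel_name"].astype(str), df["group"])))


def default_layout(channel_names: list[str]) -> SensorGroupLayout:
    """Stand-in partition: 8 contiguous, near-equal groups in channel order.

    Real sensor layouts should use :func:`layout_from_positions` or a
    layout CSV; this default only guarantees a valid, documented 8-way
    split for position-free (e.g. synthetic) cohorts.
    """
    c = len(channel_names)
    if c < 8:
        raise ValidationError(f"need >= 8 channels for 8 groups, got {c}")
    bounds = np.linspace(0, c, 9).round().astype(int)
    mapping = {}
    for g, (lo, hi) in zip(SENSOR_GROUPS, zip(bounds[:-1], bounds[1:])):
        for name in channel_names[lo:hi]:
            mapping[name] = g
    return SensorGroupLayout(mapping)


def layout_from_positions(channel_names: list[str],
                          positions: np.ndarray) -> SensorGroupLayout:
    """Octant partition from 2-D sensor positions (x: left-right, y:
    posterior-anterior): hemisphere by the sign of x, lobe band (frontal /
    temporal / parietal / occipital) by y quartile."""
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (len(channel_names), 2):
        raise ValidationError("positions must be [C, 2] (x, y)")
    y = pos[:, 1]
    qs = np.quantile(y, [0.25, 0.5, 0.75])
    bands = ("O", "T", "P", "F")  # posterior -> anterior
    mapping = {}
    for name, (x, yy) in zip(channel_names, pos):
        band = bands[int(np.searchsorted(qs, yy, side="right"))]
        mapping[name] = ("L" if x <= 0 else "R") + band
    return SensorGroupLayout(mapping)


def _block_vector(payload: np.ndarray, ia: np.ndarray, ib: np.ndarray,
                  same: bool) -> np.ndarray:
    if same:
        sub = payload[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        return sub[iu]
    return payload[np.ix_(ia, ib)].ravel()


def sp_block(sp: BrainprintFeature, group_a: str, group_b: str,
             layout: SensorGroupLayout) -> np.ndarray:
    """The (group_a, group_b) block of a spatial correlation matrix,
    vectorized (within-group: upper triangle; between-group: full block)."""
    if sp.kind != "sp" or sp.channel_names is None:
        raise ValueError("sp_block needs an sp feature with channel names")
    ia = layout.indices(group_a, sp.channel_names)
    ib = layout.indices(group_b, sp.channel_names)
    return _block_vector(sp.payload, ia, ib, group_a == group_b)


def tp_block(tp: BrainprintFeature, seg_a: int, seg_b: int,
             n_segments: int = 10) -> np.ndarray:
    """The (seg_a, seg_b) segment block of a temporal correlation matrix.

    Segments are 1-based consecutive windows of T / n_segments time points
    (so on T=100 with 10 segments, (1, 2) is rows 1-10 x columns 11-20 in
    1-based terms).
    """
    if tp.kind != "tp":
        raise ValueError("tp_block needs a tp feature")
    t = tp.payload.shape[0]
    if t % n_segments != 0:
        raise ValueError(f"T={t} not divisible into {n_segments} segments")
    for seg in (seg_a, seg_b):
        if not 1 <= seg <= n_segments:
            raise ValueError(f"segment {seg} outside [1, {n_segments}]")
    w = t // n_segments
    ia = np.arange((seg_a - 1) * w, seg_a * w)
    ib = np.arange((seg_b - 1) * w, seg_b * w)
    return _block_vector(tp.payload, ia, ib, seg_a == seg_b)


def _window_bins(freq_bins: np.ndarray, f_start: float,
                 width_hz: float = 10.0) -> np.ndarray:
    df = float(freq_bins[1] - freq_bins[0])
    on_grid = abs(f_start / df - round(f_start / df)) < 1e-9
    if not on_grid or f_start < 0 or f_start + width_hz > freq_bins[-1] + 1e-9:
        grid_max = freq_bins[-1] - width_hz
        raise ValueError(
            f"f_start must lie on the {df} Hz grid within [0, {grid_max}]; "
            f"got {f_start}"
        )
    sel = (freq_bins >= f_start - 1e-9) & (freq_bins <= f_start + width_hz + 1e-9)
    return np.nonzero(sel)[0]


def fq_window(fq: BrainprintFeature, f_start: float,
              width_hz: float = 10.0) -> np.ndarray:
    """The slice of the power vector covering [f_start, f_start + width] Hz
    inclusive (6 bins for a 10 Hz window on the 2 Hz grid)."""
    if fq.kind != "fq" or fq.freq_bins_hz is None:
        raise ValueError("fq_window needs an fq feature with bin frequencies")
    return fq.payload[_window_bins(fq.freq_bins_hz, f_start, width_hz)]


def fq_band(fq: BrainprintFeature, band: str) -> np.ndarray:
    """The slice of the power vector covering a canonical band."""
    if band not in CANONICAL_BANDS:
        raise ValueError(f"unknown band {band!r}; expected {list(CANONICAL_BANDS)}")
    lo, hi = CANONICAL_BANDS[band]
    sel = (fq.freq_bins_hz >= lo) & (fq.freq_bins_hz < hi)
    if not sel.any():
        raise ValueError(f"band {band!r} covers no bins")
    return fq.payload[sel]


def _grid_components(feature_kind: str, vector_len: int, C: int, T: int,
                     freq_bins: np.ndarray | None, n_segments: int,
                     layout: SensorGroupLayout | None,
                     channel_names: list[str] | None,
                     window_hz: float):
    """Enumerate (label_a, label_b, index-array-into-vector) components."""
    comps = []
    if feature_kind == "sp":
        # indices into the upper-triangle vectorization of the C x C matrix
        mat = np.zeros((C, C), dtype=int)
        iu = np.triu_indices(C, k=1)
        mat[iu] = np.arange(len(iu[0]))
        mat = mat + mat.T
        groups = SENSOR_GROUPS
        for a_i, ga in enumerate(groups):
            ia = layout.indices(ga, channel_names)
            for gb in groups[a_i:]:
                ib = layout.indices(gb, channel_names)
                if ga == gb:
                    if len(ia) < 3:
                        # fewer than 3 channels give a < 2-entry block on
                        # which correlation similarity is undefined
                        continue
                    sub = mat[np.ix_(ia, ia)]
                    idx = sub[np.triu_indices(len(ia), k=1)]
                else:
                    idx = mat[np.ix_(ia, ib)].ravel()
                comps.append((ga, gb, idx))
    elif feature_kind == "tp":
        mat = np.zeros((T, T), dtype=int)
        iu = np.triu_indices(T, k=1)
        mat[iu] = np.arange(len(iu[0]))
        mat = mat + mat.T
        w = T // n_segments
        for sa in range(1, n_segments + 1):
            ia = np.arange((sa - 1) * w, sa * w)
            for sb in range(sa, n_segments + 1):
                ib = np.arange((sb - 1) * w, sb * w)
                if sa == sb:
                    sub = mat[np.ix_(ia, ia)]
                    idx = sub[np.triu_indices(w, k=1)]
                else:
                    idx = mat[np.ix_(ia, ib)].ravel()
                comps.append((str(sa), str(sb), idx))
    elif feature_kind == "fq":
        df = float(freq_bins[1] - freq_bins[0])
        f = 0.0
        while f + window_hz <= freq_bins[-1] + 1e-9:
            idx = _window_bins(freq_bins, f, window_hz)
            comps.append((f"{f:g}", f"{f + window_hz:g}", idx))
            f += df
    else:
        raise ValueError(f"unknown feature kind {feature_kind!r}")
    return comps


def subfeature_accuracy_map(
    source: SessionSet, target: SessionSet, feature_kind: str,
    n: int, R: int = 100, rng: np.random.Generator | int | None = None,
    layout: SensorGroupLayout | None = None, n_segments: int = 10,
    window_hz: float = 10.0, split_fraction: float = 0.5,
    fq_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Identification accuracy of every component of one feature.

    Features are computed once per run (full protocol, same sampling and
    z-scoring as :func:`~brainprint.identify.run_identification`); each
    component's similarity and 1NN matching is then evaluated on its slice
    of the feature vector alone.

    Returns a long-format DataFrame: ``component_a``, ``component_b``
    (equal to ``component_a`` start/stop Hz for fq), ``accuracy``, ``se``,
    ``n_runs``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    individuals = protocol_individuals(source, target)
    k = len(individuals)
    blocks = target.blocks_by_individual()
    first = next(iter(blocks.values()))
    c, t = first.n_channels, first.n_times
    if feature_kind == "sp" and layout is None:
        layout = default_layout(first.channel_names)
    freq_bins = None
    if feature_kind == "fq":
        fq_kwargs = fq_kwargs or {}
        wl = fq_kwargs.get("window_len") or min(100, first.n_times)
        freq_bins = np.fft.rfftfreq(wl, d=1.0 / first.sfreq)

    comps = None
    sims_per_comp: list[np.ndarray] | None = None
    for r, (tv, sv) in enumerate(iter_run_features(
            source, target, feature_kind, n, R, rng,
            split_fraction=split_fraction, fq_kwargs=fq_kwargs)):
        if comps is None:
            comps = _grid_components(feature_kind, tv.shape[1], c, t,
                                     freq_bins, n_segments, layout,
                                     first.channel_names, window_hz)
            sims_per_comp = [np.empty((R, k, k)) for _ in comps]
        for ci, (_, _, idx) in enumerate(comps):
            sims_per_comp[ci][r] = _pearson_rows(tv[:, idx], sv[:, idx])

    rows = []
    for (la, lb, idx), sims in zip(comps, sims_per_comp):
        res = _result_from_sims(sims, individuals, individuals,
                                feature_kind, {})
        correct = res.correct.astype(float)
        se = correct.ravel().std(ddof=1) / np.sqrt(correct.size) \
            if correct.size > 1 else 0.0
        rows.append({"component_a": la, "component_b": lb,
                     "accuracy": correct.mean(), "se": se, "n_runs": R,
                     "n_entries": len(idx)})
    return pd.DataFrame(rows)
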