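"""Synthetic multi-individual, multi-session M/EEG cohort generator.

The generator instantiates the three hypothesized axes of individual
variability in sensor-space recordings:

* a **spatial** signature — a stable [C x L] mixing of L latent sources into
  C sensors, unique to each individual;
* a **temporal** signature — an evoked response (Gaussian-windowed bump)
  whose latency and width are individual-specific;
* a **spectral** signature — a damped oscillation with an individual peak
  frequency in the 6-12 Hz range riding on a 1/f background.

Session-to-session change (head repositioning, instrument drift) is modeled
as a small random perturbation of the mixing columns plus multiplicative
per-channel gain drift, resampled deterministically per (individual,
session).  ``signature_strength = 0`` collapses all individuals onto one
common signature (the null cohort); ``session_perturbation = 0`` makes
sessions statistically identical.

Every random quantity derives from ``CohortSpec.seed`` through a fixed
`numpy.random.SeedSequence` spawn-key scheme, so an entire cohort is a pure
function of its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .epochs import EpochsTensor, SessionSet, write_epochs
from .errors import ValidationError

__all__ = [
    "CohortSpec",
    "IndividualSignature",
    "Cohort",
    "draw_signatures",
    "simulate_session",
    "make_cohort",
    "degrade_cohort",
]

# Model constants (see docs/methods.md for rationale).
_AR_POLE_RADIUS = 0.97       # oscillator damping; sharper -> narrower peak
_EVOKED_AMPLITUDE = 2.5      # evoked bump amplitude relative to unit-SD sources
_EVOKED_JITTER = 0.1         # trial-to-trial evoked amplitude jitter (SD)
_BACKGROUND_AMPLITUDE = 1.0  # 1/f background SD per latent source
_GAIN_DRIFT_SCALE = 0.2      # channel gain SD per unit session_perturbation
_BASE_LATENCY_S = 0.2
_LATENCY_HALF_RANGE_S = 0.1
_BASE_WIDTH_S = 0.05
_WIDTH_LOG_SD = 0.25
_BASE_PEAK_HZ = 9.0
_PEAK_HALF_RANGE_HZ = 3.0
_BASE_PEAK_POWER = 1.5
_PEAK_POWER_LOG_SD = 0.35
_SOURCE_FREQ_JITTER_HZ = 1.5   # per-source spread of peaks around peak_freq_hz
_SOURCE_FREQ_CLIP_HZ = (5.0, 13.0)
_SOURCE_POWER_LOG_SD = 0.5     # per-source oscillation power spread

# spawn-key roots for the seed-splitting scheme
_KEY_SIGNATURES = 0
_KEY_SESSION_PERTURBATION = 1
_KEY_TRIALS = 2
_KEY_DEGRADE = 3


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``signature_strength`` scales the cross-individual dispersion of all
    signatures (0 = null cohort); ``session_perturbation`` scales the
    cross-session change of spatial mixing and channel gain; ``noise_sd`` is
    the white sensor-noise SD.
    """

    K: int = 8
    S: int = 2
    C: int = 24
    T: int = 100
    N: int = 150
    sfreq: float = 200.0
    L: int = 8
    signature_strength: float = 1.0
    session_perturbation: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValidationError(f"K must be >= 2, got {self.K}")
        if self.S < 1:
            raise ValidationError(f"S must be >= 1, got {self.S}")
        if self.L > self.C:
            raise ValidationError(f"L ({self.L}) must be <= C ({self.C})")
        if self.C < 2 or self.T < 2 or self.N < 1 or self.L < 1:
            raise ValidationError("C >= 2, T >= 2, N >= 1, L >= 1 required")
        if not self.sfreq > 0:
            raise ValidationError("sfreq must be > 0")
        for name in ("signature_strength", "session_perturbation", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @property
    def channel_names(self) -> list[str]:
        return [f"SYN{i:03d}" for i in range(self.C)]

    @property
    def individual_ids(self) -> list[str]:
        return [f"sub-{k:02d}" for k in range(self.K)]

    @property
    def session_ids(self) -> list[str]:
        return [f"ses-{s:02d}" for s in range(self.S)]


@dataclass
class IndividualSignature:
    """The stable, individual-specific generative parameters.

    ``source_freq_hz`` / ``source_power`` spread the individual's
    oscillatory peak over the L latent sources (a multi-peak spectral
    fingerprint centered on ``peak_freq_hz`` with overall scale
    ``peak_power``); when omitted they default to the scalar values for
    every source.
    """

    individual_id: str
    index: int
    mixing: np.ndarray          # [C, L], unit-norm columns
    latency_s: float            # evoked latency, in [0.1, 0.3] s
    template_width_s: float     # evoked Gaussian width (s)
    peak_freq_hz: float         # oscillatory peak, in [6, 12] Hz
    peak_power: float           # oscillation SD relative to background
    source_freq_hz: np.ndarray | None = None   # [L]
    source_power: np.ndarray | None = None     # [L]

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        norms = np.linalg.norm(self.mixing, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValidationError("mixing columns must be unit-norm")
        if not 0.1 <= self.latency_s <= 0.3:
            raise ValidationError(f"latency_s {self.latency_s} outside [0.1, 0.3]")
        if not 6.0 <= self.peak_freq_hz <= 12.0:
            raise ValidationError(
                f"peak_freq_hz {self.peak_freq_hz} outside [6, 12]"
            )
        if self.template_width_s <= 0 or self.peak_power < 0:
            raise ValidationError("width must be > 0, peak_power >= 0")
        l = self.mixing.shape[1]
        if self.source_freq_hz is None:
            self.source_freq_hz = np.full(l, self.peak_freq_hz)
        if self.source_power is None:
            self.source_power = np.full(l, self.peak_power)
        self.source_freq_hz = np.asarray(self.source_freq_hz, dtype=np.float64)
        self.source_power = np.asarray(self.source_power, dtype=np.float64)
        if self.source_freq_hz.shape != (l,) or self.source_power.shape != (l,):
            raise ValidationError("per-source freq/power must have length L")
        if (self.source_power < 0).any():
            raise ValidationError("source_power must be >= 0")


def _unit_columns(m: np.ndarray) -> np.ndarray:
    return m / np.linalg.norm(m, axis=0, keepdims=True)


def _rng_for(spec: CohortSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=key))


def draw_signatures(
    spec: CohortSpec, rng: np.random.Generator | None = None,
) -> list[IndividualSignature]:
    """Draw the K individual signatures for a cohort.

    All individual deviations from the common base are scaled by
    ``signature_strength`` (bounded parameters use ``min(strength, 1)`` so
    their invariant ranges hold); strength 0 yields K identical signatures.
    """
    rng = rng if rng is not None else _rng_for(spec, _KEY_SIGNATURES)
    s = spec.signature_strength
    s1 = min(s, 1.0)
    base_mixing = rng.standard_normal((spec.C, spec.L))
    # latency and peak frequency are assigned by permuted even spacing with
    # jitter: a cohort of distinct individuals, with pairwise separation
    # (not just dispersion) scaling with signature_strength
    grid = np.linspace(-1.0, 1.0, spec.K) if spec.K > 1 else np.zeros(1)
    lat_slots = grid[rng.permutation(spec.K)]
    freq_slots = grid[rng.permutation(spec.K)]
    sigs = []
    for k, ind in enumerate(spec.individual_ids):
        dev = rng.standard_normal((spec.C, spec.L))
        mixing = _unit_columns(base_mixing + s * dev)
        latency = _BASE_LATENCY_S + s1 * (
            0.9 * _LATENCY_HALF_RANGE_S * lat_slots[k]
            + rng.uniform(-0.005, 0.005))
        width = _BASE_WIDTH_S * np.exp(_WIDTH_LOG_SD * s1 * rng.standard_normal())
        freq = _BASE_PEAK_HZ + s1 * (
            0.85 * _PEAK_HALF_RANGE_HZ * freq_slots[k]
            + rng.uniform(-0.2, 0.2))
        power = _BASE_PEAK_POWER * np.exp(
            _PEAK_POWER_LOG_SD * s1 * rng.standard_normal())
        src_freq = np.clip(
            freq + s1 * rng.uniform(-_SOURCE_FREQ_JITTER_HZ,
                                    _SOURCE_FREQ_JITTER_HZ, spec.L),
            *_SOURCE_FREQ_CLIP_HZ)
        src_power = power * np.exp(
            _SOURCE_POWER_LOG_SD * s1 * rng.standard_normal(spec.L))
        sigs.append(IndividualSignature(
            individual_id=ind, index=k, mixing=mixing, latency_s=latency,
            template_width_s=width, peak_freq_hz=freq, peak_power=power,
            source_freq_hz=src_freq, source_power=src_power))
    return sigs


def _ar2_sources(freqs_hz: np.ndarray, sfreq: float, r: float,
                 shape: tuple[int, int, int],
                 rng: np.random.Generator) -> np.ndarray:
    """Unit-SD damped-oscillator (AR(2) resonance) noise per latent source,
    stochastic phase per trial.  ``freqs_hz`` gives one peak per source."""
    l = shape[0]
    out = np.empty(shape)
    white = rng.standard_normal(shape)
    for i in range(l):
        theta = 2.0 * np.pi * float(freqs_hz[i]) / sfreq
        a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
        x = _signal.lfilter([1.0], a, white[i], axis=-1)
        sd = x.std()
        out[i] = x / sd if sd > 0 else x
    return out


def _pink_noise(shape: tuple[int, ...], sfreq: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f-power background noise (spectral shaping of white noise)."""
    t = shape[-1]
    freqs = np.fft.rfftfreq(t, d=1.0 / sfreq)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # flat below 1 Hz
    w = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    x = np.fft.irfft(w * amp, n=t, axis=-1)
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_session(
    signature: IndividualSignature,
    spec: CohortSpec,
    session_index: int,
    rng: np.random.Generator | None = None,
    mode: str = "task",
) -> EpochsTensor:
    """Simulate one (individual, session) block of N trials.

    Latent sources = damped oscillation at the individual's peak frequency
    (stochastic phase per trial) + 1/f background + (in "task" mode) the
    individual's evoked template.  Sensors = session-perturbed mixing x
    sources x session gain + white noise.  The session perturbation depends
    only on (spec.seed, individual, session); trial-level randomness comes
    from ``rng``.
    """
    if mode not in ("task", "rest"):
        raise ValueError(f"mode must be task|rest, got {mode!r}")
    if rng is None:
        rng = _rng_for(spec, _KEY_TRIALS, signature.index, session_index)
    c, t, n, l = spec.C, spec.T, spec.N, spec.L

    prng = _rng_for(spec, _KEY_SESSION_PERTURBATION, signature.index,
                    session_index)
    mix = _unit_columns(
        signature.mixing
        + spec.session_perturbation * prng.standard_normal((c, l)) / np.sqrt(c)
    )
    gain = 1.0 + _GAIN_DRIFT_SCALE * spec.session_perturbation \
        * prng.standard_normal(c)
    gain = np.clip(gain, 0.1, None)

    sources = signature.source_power[:, None, None] * _ar2_sources(
        signature.source_freq_hz, spec.sfreq, _AR_POLE_RADIUS, (l, n, t), rng)
    sources += _BACKGROUND_AMPLITUDE * _pink_noise((l, n, t), spec.sfreq, rng)
    if mode == "task":
        times = np.arange(t) / spec.sfreq
        bump = np.exp(-0.5 * ((times - signature.latency_s)
                              / signature.template_width_s) ** 2)
        trial_amp = 1.0 + _EVOKED_JITTER * rng.standard_normal(n)
        sources += _EVOKED_AMPLITUDE * trial_amp[None, :, None] * bump[None, None, :]

    sensors = np.einsum("cl,lnt->cnt", mix, sources)
    sensors *= gain[:, None, None]
    sensors += spec.noise_sd * rng.standard_normal((c, n, t))

    return EpochsTensor(
        data=np.moveaxis(sensors, 1, 2),  # [C, T, N]
        sfreq=spec.sfreq,
        channel_names=spec.channel_names,
        individual_id=signature.individual_id,
        session_id=spec.session_ids[session_index],
        modality="SYNTH",
        time_zero_index=0,
    )


@dataclass
class Cohort:
    """A fully realized synthetic cohort: K x S epoch blocks plus the
    ground-truth signatures and a manifest."""

    spec: CohortSpec
    signatures: list[IndividualSignature]
    blocks: dict[tuple[str, str], EpochsTensor]
    modes: list[str]
    manifest: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def session_set(self, session_id: str, role: str = "source") -> SessionSet:
        sel = {k: v for k, v in self.blocks.items() if k[1] == session_id}
        return SessionSet(blocks=sel, role=role)

    def pair(self, source_session: str, target_session: str
             ) -> tuple[SessionSet, SessionSet]:
        return (self.session_set(source_session, "source"),
                self.session_set(target_session, "target"))


def make_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
    signatures: Sequence[IndividualSignature] | None = None,
    modes: Sequence[str] | None = None,
) -> Cohort:
    """Generate the full K x S cohort (optionally writing it to disk).

    ``modes`` gives the recording mode per session ("task" or "rest",
    default all "task"), enabling cross-task experiments.  ``signatures``
    may be supplied to plant bespoke structure; by default they are drawn
    from the spec.  With ``out_dir`` set, each block is written as an HDF5
    epochs file and a ``manifest.csv`` lists files, identities and
    ground-truth signature parameters.
    """
    if signatures is None:
        signatures = draw_signatures(spec)
    if len(signatures) != spec.K:
        raise ValidationError(
            f"{len(signatures)} signatures for K={spec.K} individuals")
    modes = list(modes) if modes is not None else ["task"] * spec.S
    if len(modes) != spec.S:
        raise ValidationError(f"{len(modes)} modes for S={spec.S} sessions")

    blocks: dict[tuple[str, str], EpochsTensor] = {}
    rows = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for sig in signatures:
        for s, ses in enumerate(spec.session_ids):
            blk = simulate_session(sig, spec, s, mode=modes[s])
            blocks[(sig.individual_id, ses)] = blk
            fname = f"{sig.individual_id}_{ses}.h5"
            if out_path is not None:
                write_epochs(blk, out_path / fname)
            rows.append({
                "individual_id": sig.individual_id,
                "session_id": ses,
                "file": fname,
                "mode": modes[s],
                "latency_s": sig.latency_s,
                "template_width_s": sig.template_width_s,
                "peak_freq_hz": sig.peak_freq_hz,
                "peak_power": sig.peak_power,
            })
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return Cohort(spec=spec, signatures=list(signatures), blocks=blocks,
                  modes=modes, manifest=manifest)


def degrade_cohort(cohort: Cohort, noise_sd: float,
                   seed_offset: int = 0) -> Cohort:
    """Return a copy with session-specific additive channel noise layered on
    top — an analogue of "raw" (unpreprocessed) data for preprocessing
    comparisons.

    Each (individual, session) block receives white noise of SD ``noise_sd``
    plus a session-specific per-channel offset pattern of the same scale,
    deterministically derived from the cohort seed.
    """
    blocks = {}
    for (ind, ses), blk in cohort.blocks.items():
        k = cohort.spec.individual_ids.index(ind)
        s = cohort.spec.session_ids.index(ses)
        rng = _rng_for(cohort.spec, _KEY_DEGRADE, seed_offset, k, s)
        pattern = noise_sd * rng.standard_normal(blk.n_channels)
        noisy = blk.data + noise_sd * rng.standard_normal(blk.data.shape) \
            + pattern[:, None, None]
        blocks[(ind, ses)] = replace(blk, data=noisy)
    return Cohort(spec=cohort.spec, signatures=cohort.signatures,
                  blocks=blocks, modes=cohort.modes, manifest=cohort.manifest)
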