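"""Brainprint features against brute-force oracles and their invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import get_window
from scipy.stats import pearsonr
from sklearn.base import clone

from brainprint import (BrainprintExtractor, compute_fq, compute_sp,
                        compute_tp, sample_trials, zscore_by_channel)
from brainprint.errors import DegenerateDataError

from conftest import make_tensor


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_corr(rows):
    """Pairwise Pearson correlation via scipy.stats.pearsonr, entry by entry."""
    k = rows.shape[0]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pearsonr(rows[i], rows[j]).statistic
    return out


def tapered_periodogram(x, sfreq, window_len, alpha):
    """Direct one-sided density periodogram of one segment with a Tukey taper."""
    w = get_window(("tukey", alpha), window_len)
    spec = np.abs(np.fft.rfft(x * w)) ** 2 / (sfreq * np.sum(w ** 2))
    spec[1:] *= 2.0
    if window_len % 2 == 0:
        spec[-1] /= 2.0
    return spec


# ---------------------------------------------------------------------------

class TestZscore:
    def test_mean_zero_sd_one(self, toy_tensor):
        z = zscore_by_channel(toy_tensor)
        flat = z.data.reshape(z.n_channels, -1)
        assert np.abs(flat.mean(axis=1)).max() < 1e-10
        assert np.abs(flat.std(axis=1) - 1.0).max() < 1e-10

    def test_idempotent(self, toy_tensor):
        once = zscore_by_channel(toy_tensor)
        twice = zscore_by_channel(once)
        assert np.abs(once.data - twice.data).max() < 1e-10

    def test_constant_channel_raises(self):
        t = make_tensor(c=3)
        t.data[1] = 5.0
        with pytest.raises(DegenerateDataError, match="ch1"):
            zscore_by_channel(t)


class TestSampleTrials:
    def test_full_sample_is_permutation(self, toy_tensor, rng):
        out = sample_trials(toy_tensor, toy_tensor.n_trials, rng)
        # every original trial present exactly once
        orig = {toy_tensor.data[:, :, i].tobytes()
                for i in range(toy_tensor.n_trials)}
        got = {out.data[:, :, i].tobytes() for i in range(out.n_trials)}
        assert got == orig

    def test_bounds_checked(self, toy_tensor, rng):
        with pytest.raises(ValueError):
            sample_trials(toy_tensor, toy_tensor.n_trials + 1, rng)
        with pytest.raises(ValueError):
            sample_trials(toy_tensor, 0, rng)

    def test_uniform_inclusion_frequency(self):
        t = make_tensor(n=8)
        t.data[0, 0, :] = np.arange(8)
        counts = np.zeros(8)
        for seed in range(4000):
            out = sample_trials(t, 2, np.random.default_rng(seed))
            for v in out.data[0, 0, :]:
                counts[int(v)] += 1
        freq = counts / 4000
        assert np.abs(freq - 0.25).max() < 0.03  # ~4 SE


class TestCorrelationFeatures:
    @given(st.integers(2, 6), st.integers(2, 6), st.integers(1, 6),
           st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_sp_tp_match_brute_force(self, c, t, n, seed):
        tensor = make_tensor(c=c, t=t, n=n, seed=seed)
        sp = compute_sp(tensor).payload
        assert np.abs(sp - brute_force_corr(
            tensor.data.reshape(c, -1))).max() < 1e-12
        tp = compute_tp(tensor).payload
        assert np.abs(tp - brute_force_corr(
            np.moveaxis(tensor.data, 1, 0).reshape(t, -1))).max() < 1e-12

    def test_sp_affine_invariance(self):
        # per-channel positive affine transforms (hence z-scoring) leave
        # the correlation features unchanged
        t = make_tensor(c=5, t=20, n=4, seed=1)
        sp_ref = compute_sp(t).payload
        tp_ref = compute_tp(t).payload
        scale = np.array([2.0, 0.5, 0.1, 7.0, 3.0])[:, None, None]
        shift = np.array([-1.0, 0.0, 4.0, 2.0, -3.0])[:, None, None]
        t2 = make_tensor(c=5, t=20, n=4, seed=1)
        t2.data = t2.data * scale + shift
        assert np.abs(compute_sp(t2).payload - sp_ref).max() < 1e-10
        z = zscore_by_channel(t2)
        assert np.abs(compute_sp(z).payload - sp_ref).max() < 1e-10
        # tp is NOT generally invariant to channel scaling, but is to a
        # common affine transform
        t3 = make_tensor(c=5, t=20, n=4, seed=1)
        t3.data = 3.0 * t3.data - 2.0
        assert np.abs(compute_tp(t3).payload - tp_ref).max() < 1e-10

    def test_exact_linear_dependence(self):
        t = make_tensor(c=3, t=10, n=2, seed=2)
        t.data[2] = 2.0 * t.data[1] + 1.0
        assert abs(compute_sp(t).payload[1, 2] - 1.0) < 1e-12

    def test_permutation_invariances(self, rng):
        t = make_tensor(c=5, t=12, n=6, seed=3)
        sp_ref = compute_sp(t).payload
        tp_ref = compute_tp(t).payload
        fq_ref = compute_fq(t, window_len=12).payload
        perm_trials = rng.permutation(t.n_trials)
        perm_chans = rng.permutation(t.n_channels)
        t_trials = make_tensor(c=5, t=12, n=6, seed=3)
        t_trials.data = t_trials.data[:, :, perm_trials]
        assert np.abs(compute_sp(t_trials).payload - sp_ref).max() < 1e-12
        assert np.abs(compute_fq(t_trials, window_len=12).payload
                      - fq_ref).max() < 1e-12
        t_chans = make_tensor(c=5, t=12, n=6, seed=3)
        t_chans.data = t_chans.data[perm_chans]
        assert np.abs(compute_tp(t_chans).payload - tp_ref).max() < 1e-12
        assert np.abs(compute_fq(t_chans, window_len=12).payload
                      - fq_ref).max() < 1e-12

    def test_repeated_waveform_gives_all_ones_tp(self):
        wave = np.sin(np.linspace(0, 3, 10))
        data = np.tile(wave[None, :, None], (3, 1, 4))
        data += np.array([1.0, 2.0, 3.0])[:, None, None]  # channel offsets
        t = make_tensor(c=3, t=10, n=4)
        t.data = data
        assert np.abs(compute_tp(t).payload - 1.0).max() < 1e-10

    def test_degenerate_channel_raises(self):
        t = make_tensor(c=3)
        t.data[0] = 1.0
        with pytest.raises(DegenerateDataError):
            compute_sp(t)

    def test_vector_is_upper_triangle(self):
        t = make_tensor(c=4, t=8, n=3)
        feat = compute_sp(t)
        assert feat.vector.shape == (6,)
        iu = np.triu_indices(4, k=1)
        assert np.array_equal(feat.vector, feat.payload[iu])
        assert compute_sp(t, vectorize="full").vector.shape == (16,)


class TestFrequencyFeature:
    def test_bin_layout_100_samples_200_hz(self):
        t = make_tensor(c=3, t=100, n=5, sfreq=200.0)
        feat = compute_fq(t)
        assert feat.payload.shape == (51,)
        assert np.array_equal(feat.freq_bins_hz, np.arange(0, 101, 2.0))

    def test_zero_signal_zero_power(self):
        t = make_tensor(c=2, t=100, n=2)
        t.data = np.zeros_like(t.data)
        assert np.all(compute_fq(t).payload == 0.0)

    def test_sinusoid_peak_bin(self):
        time = np.arange(100) / 200.0
        wave = np.sin(2 * np.pi * 10.0 * time)
        t = make_tensor(c=2, t=100, n=3, sfreq=200.0)
        t.data = np.tile(wave[None, :, None], (2, 1, 3))
        feat = compute_fq(t)
        assert feat.freq_bins_hz[feat.payload.argmax()] == 10.0

    def test_matches_direct_periodogram_oracle(self):
        t = make_tensor(c=3, t=100, n=4, sfreq=200.0, seed=11)
        feat = compute_fq(t, window_len=100, tukey_alpha=0.25)
        oracle = np.mean(
            [tapered_periodogram(t.data[c, :, j], 200.0, 100, 0.25)
             for c in range(3) for j in range(4)], axis=0)
        assert np.abs(feat.payload - oracle).max() < 1e-12

    def test_longer_trials_tiled(self):
        t = make_tensor(c=2, t=110, n=3, sfreq=200.0)
        feat = compute_fq(t, window_len=100)
        assert feat.payload.shape == (51,)

    def test_window_longer_than_trial_rejected(self):
        t = make_tensor(c=2, t=50, n=2)
        with pytest.raises(ValueError):
            compute_fq(t, window_len=100)

    def test_total_power_monotone_in_noise_sd(self):
        totals = []
        for sd in (0.5, 1.0, 2.0, 4.0):
            t = make_tensor(c=2, t=100, n=10, seed=5)
            t.data = sd * t.data
            totals.append(compute_fq(t).payload.sum())
        assert all(a < b for a, b in zip(totals, totals[1:]))


class TestExtractor:
    def test_transform_shape_and_params(self, small_cohort):
        blocks = [small_cohort.blocks[(ind, "ses-00")]
                  for ind in small_cohort.spec.individual_ids]
        ext = BrainprintExtractor(kind="sp", n_trials=20, random_state=0)
        X = ext.fit(blocks).transform(blocks)
        assert X.shape == (4, 16 * 15 // 2)
        cloned = clone(ext)
        assert cloned.get_params()["n_trials"] == 20

    def test_accepts_raw_arrays(self):
        rng = np.random.default_rng(0)
        X = BrainprintExtractor(kind="tp").fit_transform(
            [rng.standard_normal((4, 10, 3)) for _ in range(2)])
        assert X.shape == (2, 45)
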