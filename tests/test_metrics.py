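"""Accuracy metrics, differential identifiability and significance tests."""

import numpy as np
import pytest
from scipy import stats

from brainprint import (chance_levels, confusion_matrix,
                        differential_identifiability,
                        differential_identifiability_result,
                        identification_accuracy, permutation_pvalue,
                        rank_accuracy, unpaired_t_test)
from brainprint.errors import DegenerateDataError
from brainprint.identify import IdentificationResult, _result_from_sims


def fabricate_result(sims, feature="sp"):
    """Build an IdentificationResult straight from an [R, K, K] array."""
    sims = np.asarray(sims, dtype=float)
    ids = [f"sub-{i}" for i in range(sims.shape[1])]
    return _result_from_sims(sims, ids, ids, feature, {})


def random_result(r, k, rng):
    return fabricate_result(rng.standard_normal((r, k, k)))


class TestIdentificationAccuracy:
    def test_all_correct(self, rng):
        res = fabricate_result(np.tile(np.eye(3), (5, 1, 1))
                               + 0.01 * rng.standard_normal((5, 3, 3)))
        assert identification_accuracy(res).identification_accuracy[0] > 0.99

    def test_hand_built_three_of_four(self):
        # K=2, R=4: target 0 correct in 3 of 4 runs, target 1 always correct
        sims = np.array([
            [[0.9, 0.1], [0.1, 0.9]],
            [[0.9, 0.1], [0.1, 0.9]],
            [[0.9, 0.1], [0.1, 0.9]],
            [[0.1, 0.9], [0.1, 0.9]],
        ])
        res = fabricate_result(sims)
        indiv = identification_accuracy(res, "individual")
        assert indiv.identification_accuracy.tolist() == [0.75, 1.0]
        pooled = identification_accuracy(res, "pooled")
        assert pooled.identification_accuracy[0] == pytest.approx(0.875)

    def test_uniform_random_near_chance(self, rng):
        res = random_result(400, 8, rng)
        acc = identification_accuracy(res).identification_accuracy[0]
        assert abs(acc - 0.125) < 3 * np.sqrt(0.125 * 0.875 / (400 * 8))


class TestRankAccuracy:
    def test_extremes(self):
        v = np.array([[0.9, 0.1, 0.2],
                      [0.4, 0.8, 0.3],
                      [0.1, 0.0, 0.9]])
        assert np.all(rank_accuracy(v) == 1.0)
        w = 1.0 - v  # diagonal now strictly minimal in each row
        assert np.all(rank_accuracy(w) == pytest.approx(1.0 / 3.0))

    def test_random_rows_chance_level(self, rng):
        # chance rank accuracy for K=4 is (K+1)/(2K) = 0.625
        vals = rng.standard_normal((4000, 4, 4))
        means = np.mean([rank_accuracy(v).mean() for v in vals])
        assert abs(means - 0.625) < 0.01

    def test_ties_midranked(self):
        v = np.full((3, 3), 0.5)
        assert np.all(rank_accuracy(v) == pytest.approx(2.0 / 3.0))


class TestDifferentialIdentifiability:
    def test_flat_matrix_is_zero(self):
        assert differential_identifiability(np.full((5, 5), 0.3)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_identity_gap_is_hundred(self):
        assert differential_identifiability(np.eye(4)) == pytest.approx(100.0)

    def test_hand_evaluated_k3(self):
        c = np.array([[0.8, 0.2, 0.1],
                      [0.0, 0.6, 0.3],
                      [0.4, 0.1, 0.7]])
        expected = 100.0 * (np.trace(c) / 3
                            - (c.sum() - np.trace(c)) / 6)
        assert abs(differential_identifiability(c) - expected) < 1e-12

    def test_constant_shift_invariance(self, rng):
        c = rng.standard_normal((5, 5))
        assert differential_identifiability(c + 7.0) == pytest.approx(
            differential_identifiability(c), abs=1e-9)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            differential_identifiability(np.zeros((3, 4)))

    def test_result_level_aggregation(self, rng):
        res = random_result(20, 4, rng)
        per_run, se = differential_identifiability_result(res)
        averaged, _ = differential_identifiability_result(res, per_run=False)
        # both estimate the same population quantity (equal for linear stats)
        assert per_run == pytest.approx(averaged, abs=1e-9)
        assert se >= 0


class TestChanceLevels:
    @pytest.mark.parametrize("k, ident, rank", [
        (8, 0.125, 0.5625),
        (4, 0.25, 0.625),
        (15, 1.0 / 15.0, 16.0 / 30.0),
    ])
    def test_printed_values(self, k, ident, rank):
        ch = chance_levels(k)
        assert ch.identification == pytest.approx(ident)
        assert ch.rank == pytest.approx(rank)
        assert ch.differential == 0.0

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            chance_levels(1)


class TestConfusion:
    def test_perfect_is_scaled_identity(self, rng):
        res = fabricate_result(np.tile(np.eye(4), (7, 1, 1))
                               + 0.01 * rng.standard_normal((7, 4, 4)))
        cm = confusion_matrix(res)
        assert np.array_equal(cm.values, 7 * np.eye(4, dtype=int))

    def test_rows_sum_to_runs(self, rng):
        res = random_result(31, 5, rng)
        assert np.all(confusion_matrix(res).values.sum(axis=1) == 31)

    def test_uniform_assignments_spread(self, rng):
        res = random_result(2000, 4, rng)
        cm = confusion_matrix(res).values
        assert np.abs(cm / 2000 - 0.25).max() < 0.05


class TestPermutation:
    def test_minimal_p_for_perfect_identification(self, rng):
        sims = np.tile(np.eye(8), (100, 1, 1)) \
            + 0.01 * rng.standard_normal((100, 8, 8))
        res = fabricate_result(sims)
        out = permutation_pvalue(res, B=4999, rng=1)
        assert out.observed == 1.0
        assert out.p_value == pytest.approx(1.0 / 5000.0)

    def test_b_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_pvalue(random_result(3, 3, rng), B=0)

    def test_null_pvalues_mostly_nonsignificant(self):
        ps = [permutation_pvalue(
                  random_result(30, 6, np.random.default_rng(seed)),
                  B=99, rng=seed).p_value
              for seed in range(40)]
        assert np.mean(np.array(ps) > 0.05) >= 0.9

    def test_null_pvalues_uniform(self):
        # calibration: under exchangeable runs the p-value is uniform
        ps = [permutation_pvalue(
                  random_result(40, 8, np.random.default_rng(seed)),
                  B=99, rng=10_000 + seed).p_value
              for seed in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestTTest:
    def test_identical_vectors(self):
        a = np.array([0.1, 0.5, 0.9, 0.3])
        t, p = unpaired_t_test(a, a.copy())
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_reference_implementation(self, rng):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest
        a = rng.standard_normal(48) + 0.3
        b = rng.standard_normal(48)
        t, p = unpaired_t_test(a, b)
        t_ref, p_ref, _ = sm_ttest(a, b, usevar="pooled")
        assert abs(t - t_ref) < 1e-10
        assert abs(p - p_ref) < 1e-10

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            unpaired_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1.0, 2.0])
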