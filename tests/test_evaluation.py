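"""Accuracy metric, permutation nulls, ROI summaries, noise ceilings."""

import numpy as np
import pytest
from scipy.stats import binom

from ventralenc import (
    advantage_permutation_threshold,
    model_advantage,
    noise_ceiling,
    prediction_accuracy,
    randomization_threshold,
    roi_summary,
)
from ventralenc.evaluation import simulate_ceiling


class TestPredictionAccuracy:
    def test_identity_and_antisymmetry(self):
        r = np.array([0.3, -1.2, 0.8, 2.0])
        assert prediction_accuracy(r, r) == pytest.approx(1.0)
        assert prediction_accuracy(r, -r) == pytest.approx(-1.0)

    def test_textbook_formula(self):
        # direct evaluation of the product-moment formula gives 0.6
        assert prediction_accuracy([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_returns_zero(self):
        assert prediction_accuracy([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]) == 0.0

    def test_length_mismatch_and_short_inputs_raise(self):
        with pytest.raises(ValueError):
            prediction_accuracy([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            prediction_accuracy([1, 2], [1, 2])


class TestRandomizationThreshold:
    def test_median_of_symmetric_null_near_zero(self, rng):
        sig = randomization_threshold(
            rng.standard_normal((20, 100)),
            rng.standard_normal((20, 100)),
            n_perm=1000,
            alpha=0.5,
            seed=rng,
        )
        assert abs(sig.threshold) < 0.05

    def test_null_moments_match_exchangeability_theory(self, rng):
        """The permutation null of rho has mean 0 (each permuted entry is
        marginally uniform over a zero-mean standardized vector) and variance
        1/(n-1)."""
        n = 50
        sig = randomization_threshold(
            rng.standard_normal((n, 100)),
            rng.standard_normal((n, 100)),
            n_perm=1000,
            alpha=0.001,
            seed=rng,
        )
        assert sig.null_mean == pytest.approx(0.0, abs=0.01)
        assert sig.null_var == pytest.approx(1 / (n - 1), rel=0.10)

    def test_zero_variance_predictions_never_pass(self, rng):
        measured = rng.standard_normal((30, 10))
        sig = randomization_threshold(
            measured, np.zeros((30, 10)), n_perm=200, alpha=0.5, seed=0
        )
        assert not sig.mask.any()

    def test_per_voxel_pooling_gives_vector_threshold(self, rng):
        sig = randomization_threshold(
            rng.standard_normal((20, 6)),
            rng.standard_normal((20, 6)),
            n_perm=200,
            alpha=0.05,
            pooling="per-voxel",
            seed=1,
        )
        assert np.shape(sig.threshold) == (6,)
        assert sig.mask.shape == (6,)

    def test_preconditions(self, rng):
        x = rng.standard_normal((2, 4))
        with pytest.raises(ValueError):
            randomization_threshold(x, x, n_perm=200)
        y = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            randomization_threshold(y, y, n_perm=50)


class TestROISummary:
    def test_pools_top_k_across_subjects(self, rng):
        accs = {s: rng.uniform(size=120) for s in range(5)}
        mean, var = roi_summary(accs, top_k=100)
        pooled = np.concatenate([np.sort(a)[-100:] for a in accs.values()])
        assert pooled.size == 500
        assert mean == pytest.approx(pooled.mean())
        assert var == pytest.approx(pooled.var(ddof=1))

    def test_constant_accuracies(self):
        mean, var = roi_summary({"s1": np.full(10, 0.7)}, top_k=5)
        assert mean == pytest.approx(0.7)
        assert var == pytest.approx(0.0)

    def test_top_1_is_max(self):
        mean, _ = roi_summary({"s1": [0.2, 0.9, 0.5]}, top_k=1)
        assert mean == pytest.approx(0.9)

    def test_small_roi_uses_all(self):
        mean, _ = roi_summary({"s1": [0.2, 0.4]}, top_k=10)
        assert mean == pytest.approx(0.3)


class TestModelAdvantage:
    def test_uniform_advantage(self):
        acc_b = np.linspace(0.5, 0.9, 20)
        res = model_advantage(acc_b + 0.1, acc_b, np.ones(20, bool), np.ones(20, bool))
        assert res.fraction_a == 100.0
        assert res.fraction_b == 0.0

    def test_ties_split_evenly(self):
        acc = np.full(10, 0.6)
        res = model_advantage(acc, acc, np.ones(10, bool), np.ones(10, bool))
        assert res.fraction_a == res.fraction_b == 50.0

    def test_empty_intersection_flagged_undefined(self):
        res = model_advantage([0.5], [0.6], [False], [True])
        assert res.undefined


class TestAdvantageThreshold:
    def test_single_voxel_two_point_null(self):
        assert advantage_permutation_threshold(1, 1000, 0.05, seed=0) == 100.0

    @pytest.mark.parametrize("n", [100, 500, 1000])
    def test_matches_binomial_closed_form(self, n):
        x = advantage_permutation_threshold(n, 1000, 0.05, seed=n)
        closed = 100.0 * binom.ppf(0.95, n, 0.5) / n
        assert x == pytest.approx(closed, abs=1.0)


class TestNoiseCeiling:
    def test_noiseless_runs_reach_one(self, rng):
        sig = rng.standard_normal((1, 50, 3))
        stack = np.repeat(sig, 4, axis=0)  # identical runs
        res = noise_ceiling(stack, n_sim=300, seed=0)
        assert np.all(res.ceiling >= 0.999)
        assert np.all(res.noise_var == 0.0)

    def test_clipped_signal_variance_gives_zero_ceiling(self, rng):
        """When noise variance exceeds total variance, the signal variance is
        clipped to zero and the ceiling collapses to ~0."""
        stack = rng.standard_normal((20, 40, 8))  # no stimulus signal
        res = noise_ceiling(stack, n_sim=1000, seed=1)
        clipped = res.signal_var == 0.0
        assert clipped.any()
        assert np.all(np.abs(res.ceiling[clipped]) < 0.1)

    def test_equal_signal_and_noise_sd(self):
        """sigma_s = sigma_n implies a ceiling of 1/sqrt(2)."""
        c = simulate_ceiling(0.0, 1.0, 1.0, 50, n_sim=1000, seed=2)
        assert c == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_monotone_in_run_noise(self, rng):
        sig = rng.standard_normal((50, 40))
        ceilings = []
        for sd in (0.5, 1.0, 2.0):
            noise = np.random.default_rng(7).standard_normal((35, 50, 40)) * sd
            res = noise_ceiling(sig[None] + noise, n_sim=300, seed=3)
            ceilings.append(np.median(res.ceiling))
        assert ceilings[0] >= ceilings[1] >= ceilings[2]

    def test_too_few_runs_raise(self, rng):
        with pytest.raises(ValueError):
            noise_ceiling(rng.standard_normal((1, 10, 2)))
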