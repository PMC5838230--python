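import itertools

import numpy as np
import pytest

from mmdscreen import (
    MMDScreen,
    centered_mmd_squared,
    gaussian_kernel,
    median_bandwidth,
    mmd_screen,
    mmd_squared,
    permutation_test,
    witness_function,
)
from mmdscreen.mmd import gram_matrix


def quadratic_form_mmd2(samples, signs, h):
    """Independent oracle: w^T K w over the concatenated samples with
    per-sample weights sign / n_sample."""
    stacked = np.vstack(samples)
    w = np.concatenate(
        [np.full(len(s), sign / len(s)) for s, sign in zip(samples, signs)]
    )
    sq = ((stacked[:, None, :] - stacked[None, :, :]) ** 2).sum(-1)
    K = np.exp(-sq / (2 * h * h))
    return w @ K @ w


class TestMedianBandwidth:
    def test_single_pair(self):
        assert median_bandwidth([(0.0, 0.0), (3.0, 4.0)]) == 5.0

    def test_matches_exhaustive_pair_enumeration(self, rng):
        pts = rng.normal(size=(5, 2))
        dists = [
            np.linalg.norm(pts[i] - pts[j])
            for i, j in itertools.combinations(range(5), 2)
        ]
        assert median_bandwidth(pts) == pytest.approx(np.median(dists))

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_bandwidth([(1.0, 1.0), (1.0, 1.0)])

    def test_subsampled_path_is_seeded_and_close(self, rng):
        pts = rng.normal(size=(300, 2))
        full = median_bandwidth(pts)
        sub1 = median_bandwidth(pts, max_pairs=5000, seed=1)
        sub2 = median_bandwidth(pts, max_pairs=5000, seed=1)
        assert sub1 == sub2
        assert sub1 == pytest.approx(full, rel=0.1)


class TestGaussianKernel:
    def test_analytic_values(self):
        u = np.array([1.0, 2.0])
        assert gaussian_kernel(u, u, h=0.7) == 1.0
        v = u + np.array([0.7, 0.0])  # ||u - v|| = h
        assert gaussian_kernel(u, v, h=0.7) == pytest.approx(np.exp(-0.5))

    def test_gram_is_psd(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(rng.integers(3, 15), 2))
            K = gram_matrix(pts, pts, h=1.3)
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-9

    def test_requires_positive_bandwidth(self):
        with pytest.raises(ValueError):
            gaussian_kernel([0.0], [1.0], h=0.0)


class TestMMDSquared:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=(6, 2))
        assert mmd_squared(x, x.copy(), h=1.0) == 0.0

    def test_two_singletons_analytic(self):
        d, h = 1.7, 0.9
        expected = 2 - 2 * np.exp(-(d**2) / (2 * h * h))
        assert mmd_squared([[0.0]], [[d]], h=h) == pytest.approx(expected)

    def test_matches_quadratic_form_oracle(self, rng):
        x, y = rng.normal(size=(8, 2)), rng.normal(size=(5, 2)) + 1
        oracle = quadratic_form_mmd2([x, y], [1, -1], h=1.2)
        assert mmd_squared(x, y, h=1.2) == pytest.approx(oracle, abs=1e-12)

    def test_unbiased_estimator_mean_zero_under_null(self, rng):
        # U-statistic is unbiased: its mean over null replicates ~ 0, while
        # the V-statistic is positively biased
        u_vals, v_vals = [], []
        for _ in range(300):
            x, y = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
            u_vals.append(mmd_squared(x, y, h=1.0, unbiased=True))
            v_vals.append(mmd_squared(x, y, h=1.0))
        assert abs(np.mean(u_vals)) < 0.02
        assert np.mean(v_vals) > np.mean(u_vals)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mmd_squared(np.empty((0, 2)), np.ones((3, 2)), h=1.0)


class TestCenteredMMD:
    def test_shared_control_reduces_to_plain(self, rng):
        x, y = rng.normal(size=(7, 2)), rng.normal(size=(6, 2))
        a = rng.normal(size=(5, 2))
        plain = mmd_squared(x, y, h=1.1)
        centered = centered_mmd_squared(x, a, y, a, h=1.1)
        assert centered == pytest.approx(plain, abs=1e-12)

    def test_self_centered_is_zero(self, rng):
        x, y = rng.normal(size=(5, 2)), rng.normal(size=(4, 2))
        assert centered_mmd_squared(x, x, y, y, h=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_quadratic_form_oracle(self, rng):
        samples = [rng.normal(size=(n, 2)) for n in (6, 4, 5, 3)]
        oracle = quadratic_form_mmd2(samples, [1, -1, -1, 1], h=0.8)
        assert centered_mmd_squared(*samples, h=0.8) == pytest.approx(oracle, abs=1e-12)

    def test_sqrt_is_empirically_a_metric(self, rng):
        # RKHS norm of centered embedding differences: symmetry + triangle
        # inequality on random (population, control) triples
        h = 1.0
        for _ in range(30):
            pops = [rng.normal(size=(6, 2)) for _ in range(3)]
            ctrls = [rng.normal(size=(5, 2)) for _ in range(3)]

            def d(i, j):
                return np.sqrt(
                    centered_mmd_squared(pops[i], ctrls[i], pops[j], ctrls[j], h)
                )

            assert d(0, 1) == pytest.approx(d(1, 0), abs=1e-9)
            assert d(0, 2) <= d(0, 1) + d(1, 2) + 1e-9


class TestPermutationTest:
    def test_minimum_p_when_separated(self, rng):
        x = rng.normal(size=(10, 2))
        c = rng.normal(size=(10, 2)) + 50.0  # far separated: obs beats all perms
        res = permutation_test(x, c, h=1.0, M=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_determinism(self, rng):
        x, c = rng.normal(size=(8, 2)), rng.normal(size=(9, 2))
        r1 = permutation_test(x, c, h=1.0, M=500, seed=42)
        r2 = permutation_test(x, c, h=1.0, M=500, seed=42)
        assert r1.p_value == r2.p_value and r1.mmd2 == r2.mmd2

    def test_tiny_groups_refused(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            permutation_test(rng.normal(size=(1, 2)), rng.normal(size=(5, 2)), h=1.0)

    def test_tie_rule_ge_is_more_conservative(self, rng):
        x, c = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        p_strict = permutation_test(x, c, h=1.0, M=200, seed=7).p_value
        p_ge = permutation_test(x, c, h=1.0, M=200, seed=7, tie_rule=">=").p_value
        assert p_ge >= p_strict

    def test_type_i_error_within_binomial_ci(self):
        # 400 null replicates, n = 30 per group, M = 200, alpha = 0.05
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 400
        for i in range(n_rep):
            x, c = rng.normal(size=(30, 2)), rng.normal(size=(30, 2))
            h = median_bandwidth(np.vstack([x, c]))
            if permutation_test(x, c, h=h, M=200, seed=i).p_value <= 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert abs(rate - 0.05) <= 1.96 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(123)
        rates = []
        for shift in (0.3, 1.0, 2.5):
            rejections = 0
            for i in range(60):
                x = rng.normal(size=(25, 2)) + shift
                c = rng.normal(size=(25, 2))
                h = median_bandwidth(np.vstack([x, c]))
                if permutation_test(x, c, h=h, M=200, seed=i).p_value <= 0.05:
                    rejections += 1
            rates.append(rejections / 60)
        assert rates[0] <= rates[1] + 0.1 and rates[1] <= rates[2] + 0.1
        assert rates[2] > rates[0]

    def test_scale_equivariance_of_heuristic(self, rng):
        # rescaling all inputs and recomputing the median-heuristic bandwidth
        # leaves the Gram matrix, hence the p-value, exactly unchanged
        x, c = rng.normal(size=(12, 2)), rng.normal(size=(12, 2))
        for scale in (0.01, 7.0):
            h1 = median_bandwidth(np.vstack([x, c]))
            h2 = median_bandwidth(np.vstack([x * scale, c * scale]))
            assert h2 == pytest.approx(scale * h1)
            p1 = permutation_test(x, c, h=h1, M=300, seed=5).p_value
            p2 = permutation_test(x * scale, c * scale, h=h2, M=300, seed=5).p_value
            assert p1 == p2


class TestWitnessFunction:
    def test_identical_samples_vanish(self, rng):
        x = rng.normal(size=(10, 2))
        grid = rng.normal(size=(20, 2))
        assert np.allclose(witness_function(x, x.copy(), grid, h=1.0), 0.0)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=(6, 2)), rng.normal(size=(7, 2))
        grid = rng.normal(size=(15, 2))
        f = witness_function(x, y, grid, h=1.0)
        g = witness_function(y, x, grid, h=1.0)
        assert np.allclose(f, -g)

    def test_extrema_locate_the_populations(self):
        x = np.full((30, 1), -1.0)
        y = np.full((30, 1), 1.0)
        grid = np.linspace(-3, 3, 601)[:, None]
        f = witness_function(x, y, grid, h=0.5)
        assert grid[np.argmax(f), 0] == pytest.approx(-1.0, abs=0.1)
        assert grid[np.argmin(f), 0] == pytest.approx(1.0, abs=0.1)


class TestMMDScreen:
    def test_planted_effect_found(self):
        from mmdscreen import SimConfig, scale_unit_variance, simulate_screen
        from mmdscreen.simulate import EffectSpec

        effects = {(0, 0): EffectSpec.from_class("large", shift=2.0, penetrance=1.0)}
        cfg = SimConfig(n_sets=2, structures_per_population=100, seed=21,
                        effects=effects)
        ds, _ = simulate_screen(cfg)
        fm = scale_unit_variance(ds, "none")
        # enough permutations that the attainable minimum p survives BH
        screen = MMDScreen(permutations=1000, seed=2).fit(fm)
        assert ("set01", "sh01_01") in screen.hit_populations()

    def test_results_contract(self, null_features):
        screen = MMDScreen(permutations=100, seed=3).fit(null_features)
        res = screen.results_
        assert np.all(res["p_value"] >= 1 / 101)
        assert np.allclose(res["mmd"], np.sqrt(res["mmd2"]))
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()
        assert len(res) == len(null_features.knockdowns())

    def test_wrapper_and_empty_screen(self, null_features):
        tests = mmd_screen(null_features, M=50, seed=1)
        assert len(tests) == len(null_features.knockdowns())
        import pandas as pd

        from mmdscreen.preprocessing import FeatureMatrix

        ctrl_only = null_features.frame[null_features.frame["is_control"]]
        fm = FeatureMatrix(
            frame=ctrl_only.reset_index(drop=True),
            condition="none",
            feature_sd=null_features.feature_sd,
            clip_eps=1e-6,
        )
        assert mmd_screen(fm, M=50, seed=1) == []
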