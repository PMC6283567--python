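import itertools

import numpy as np
import pytest
from scipy import stats

from rarestrat import (
    WeightSpec,
    cast_scores,
    compute_weights,
    doestrare_statistic,
    fit_null,
    kbac_statistic,
    make_fixture,
    podkat_Q,
    podkat_kernel,
    skat_Q,
    weighted_sum_scores,
)
from rarestrat.assoc import asum_signs, control_maf, doestrare_precompute


class TestScores:
    def test_cast_indicator(self):
        X = np.array([[0, 0, 0], [0, 2, 1], [1, 0, 0]])
        assert cast_scores(X).tolist() == [0.0, 1.0, 1.0]

    def test_cast_column_permutation_invariant(self, rng):
        X = rng.integers(0, 3, size=(20, 6))
        perm = rng.permutation(6)
        assert np.array_equal(cast_scores(X), cast_scores(X[:, perm]))

    def test_cast_empty_errors(self):
        with pytest.raises(ValueError):
            cast_scores(np.empty((4, 0)))

    def test_weighted_sum_hand_values(self):
        assert weighted_sum_scores(np.array([[1, 0, 2]]), np.ones(3))[0] == 3.0
        assert weighted_sum_scores(np.array([[2, 1, 1]]), np.array([0.5, 1, 0]))[0] == 2.0
        assert np.all(weighted_sum_scores(np.array([[2, 1, 1]]), np.zeros(3)) == 0)

    def test_weighted_sum_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_sum_scores(np.ones((3, 2)), np.ones(3))


class TestWeights:
    def test_uniform(self):
        X = np.zeros((4, 3))
        assert compute_weights(WeightSpec("uniform"), X, np.zeros(4)).tolist() == [1, 1, 1]

    def test_beta_weight_at_maf_zero_is_25(self):
        # Beta(1, 25) density at 0 equals 25 (closed form 25 (1-x)^24)
        X = np.zeros((10, 1))
        w = compute_weights(WeightSpec("beta_maf_total"), X, np.zeros(10))
        assert w[0] == pytest.approx(25.0)

    def test_invsd_control_pseudocount_fixture(self):
        fx = make_fixture("weights_ctrl")
        assert control_maf(fx["X"], fx["Y"])[0] == pytest.approx(fx["maf0"])
        w = compute_weights(WeightSpec("invsd_maf_controls"), fx["X"], fx["Y"])
        assert w[0] == pytest.approx(fx["weight"])

    def test_invsd_total_monomorphic_zeroed(self):
        X = np.column_stack([np.zeros(8), np.ones(8)])
        w = compute_weights(WeightSpec("invsd_maf_total"), X, np.zeros(8))
        assert w[0] == 0.0 and w[1] > 0

    def test_weights_nonnegative(self, rng):
        X = rng.integers(0, 3, size=(30, 5)).astype(float)
        Y = rng.integers(0, 2, size=30)
        for scheme in ("uniform", "beta_maf_total", "invsd_maf_total", "invsd_maf_controls"):
            assert np.all(compute_weights(WeightSpec(scheme), X, Y) >= 0)


class TestAsumSigns:
    def test_protective_variant_flagged(self):
        # variant carried only by controls, strongly
        X = np.zeros((40, 1))
        X[20:36, 0] = 2
        Y = np.zeros(40, dtype=np.int8)
        Y[:20] = 1
        null = fit_null(Y)
        signs = asum_signs(X, Y, null.mu, marginal_alpha=0.10)
        assert signs[0] == -1.0

    def test_zero_carrier_defaults_positive(self):
        X = np.zeros((10, 1))
        Y = np.array([1] * 5 + [0] * 5, dtype=np.int8)
        null = fit_null(Y)
        assert asum_signs(X, Y, null.mu)[0] == 1.0

    def test_label_flip_symmetry(self, rng):
        X = rng.integers(0, 3, size=(60, 4)).astype(float)
        Y = np.array([1] * 30 + [0] * 30, dtype=np.int8)
        rng.shuffle(Y)
        null = fit_null(Y)
        s1 = asum_signs(X, Y, null.mu)
        s2 = asum_signs(X, 1 - Y, null.mu)
        sig = s1 == -1.0
        assert np.all(s2[sig] == 1.0)


class TestKbac:
    def test_hand_instance(self):
        fx = make_fixture("kbac_4")
        stat, table = kbac_statistic(fx["X"], fx["Y"])
        assert stat == pytest.approx(fx["statistic"])
        carrier = np.flatnonzero(~table.is_wildtype)[0]
        assert table.weights[carrier] == pytest.approx(fx["carrier_weight"])
        assert table.weights[table.is_wildtype][0] == pytest.approx(1.0)

    def test_proportional_split_gives_zero(self):
        # every genotype class split evenly between cases and controls
        X = np.array([[1], [1], [0], [0]])
        Y = np.array([1, 0, 1, 0], dtype=np.int8)
        stat, _ = kbac_statistic(X, Y)
        assert stat == pytest.approx(0.0)

    def test_weights_unit_interval_and_monotone(self):
        # enumerate all case allocations of tables with N <= 8
        N, N1 = 8, 4
        for n_l in range(1, N + 1):
            w = stats.hypergeom.sf(np.arange(0, min(n_l, N1) + 1) - 1, N, n_l, N1)
            assert np.all((w >= 0) & (w <= 1.0 + 1e-12))
            assert np.all(np.diff(w) <= 1e-12)  # non-increasing in n_l1

    def test_exclude_wildtype_switch(self):
        fx = make_fixture("kbac_4")
        stat_all, _ = kbac_statistic(fx["X"], fx["Y"])
        stat_c, _ = kbac_statistic(fx["X"], fx["Y"], exclude_wildtype=True)
        # carrier-only sum: (0.5 * 0.5)^2
        assert stat_c == pytest.approx(0.0625)
        assert stat_all == pytest.approx(0.0625)


class TestSkatQ:
    def test_hand_instance_rho0(self):
        fx = make_fixture("skat_4")
        q = skat_Q(fx["X"], fx["Y"], fx["mu"], np.ones(2), rho=0.0)
        assert q == pytest.approx(fx["Q_rho0"])

    def test_rho1_equals_squared_burden(self, rng):
        X = rng.integers(0, 3, size=(12, 5)).astype(float)
        Y = rng.integers(0, 2, size=12)
        mu = np.full(12, Y.mean())
        q1 = skat_Q(X, Y, mu, np.ones(5), rho=1.0)
        s = X.sum(axis=1) @ (Y - mu)
        assert q1 == pytest.approx(s**2)

    def test_monotone_in_rho_when_scores_share_sign(self):
        # brute force over the rho grid on a 4-individual instance
        X = np.array([[2, 1], [1, 1], [0, 0], [0, 0]], dtype=float)
        Y = np.array([1, 1, 0, 0])
        mu = np.full(4, 0.5)
        qs = [skat_Q(X, Y, mu, np.ones(2), r) for r in np.linspace(0, 1, 11)]
        assert np.all(np.diff(qs) >= -1e-12)

    def test_row_permutation_invariance(self, rng):
        X = rng.integers(0, 3, size=(15, 4)).astype(float)
        Y = rng.integers(0, 2, size=15)
        mu = np.full(15, Y.mean())
        perm = rng.permutation(15)
        for rho in (0.0, 0.5, 1.0):
            assert skat_Q(X, Y, mu, np.ones(4), rho) == pytest.approx(
                skat_Q(X[perm], Y[perm], mu[perm], np.ones(4), rho)
            )


class TestPodkat:
    def test_kernel_entries(self):
        fx = make_fixture("podkat_kernel")
        k = podkat_kernel(fx["positions"], fx["radius"])
        assert np.allclose(np.diag(k.A), 1.0)
        assert k.A[0, 1] == pytest.approx(fx["A_01"])
        assert k.A[0, 2] == pytest.approx(fx["A_02"])
        assert np.allclose(k.A, k.A.T)

    def test_identity_kernel_reduces_to_skat(self, rng):
        X = rng.integers(0, 3, size=(10, 3)).astype(float)
        Y = rng.integers(0, 2, size=10)
        mu = np.full(10, Y.mean())
        # positions far apart: A = I
        k = podkat_kernel(np.array([0, 5_000, 10_000]), radius=1_000)
        assert np.allclose(k.A, np.eye(3))
        assert podkat_Q(X, Y, mu, np.ones(3), k) == pytest.approx(
            skat_Q(X, Y, mu, np.ones(3), rho=0.0)
        )

    def test_single_position_reduces_to_burden_kernel(self, rng):
        X = rng.integers(0, 3, size=(10, 3)).astype(float)
        Y = rng.integers(0, 2, size=10)
        mu = np.full(10, Y.mean())
        k = podkat_kernel(np.array([100, 100, 100]), radius=1_000)
        # A = 11' so AA' = P 11': the burden kernel scaled by P
        assert podkat_Q(X, Y, mu, np.ones(3), k) == pytest.approx(
            3.0 * skat_Q(X, Y, mu, np.ones(3), rho=1.0)
        )

    def test_two_variant_direct_matrix_oracle(self):
        X = np.array([[1, 0], [0, 2], [1, 1], [0, 0]], dtype=float)
        Y = np.array([1, 0, 1, 0])
        mu = np.full(4, 0.5)
        w = np.array([0.7, 1.3])
        k = podkat_kernel(np.array([100, 400]), radius=1_000)
        # brute-force linear algebra: (Y-mu)' X W A A' W X' (Y-mu)
        W = np.diag(w)
        r = Y - mu
        expected = r @ X @ W @ k.A @ k.A.T @ W @ X.T @ r
        assert podkat_Q(X, Y, mu, w, k) == pytest.approx(expected)


class TestDoEstRare:
    def test_symmetric_configuration_is_zero(self):
        X = np.array([[1, 0], [0, 1], [1, 0], [0, 1]], dtype=float)
        Y = np.array([1, 1, 0, 0], dtype=np.int8)
        assert doestrare_statistic(X, Y, np.array([100, 300]), 1_000) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_nonnegative(self, rng):
        X = (rng.random((30, 5)) < 0.1).astype(float)
        Y = np.array([1] * 15 + [0] * 15, dtype=np.int8)
        pos = np.sort(rng.choice(np.arange(1, 900), 5, replace=False))
        assert doestrare_statistic(X, Y, pos, 1_000) >= 0.0

    def test_empty_group_zero_density(self):
        X = np.array([[1], [0], [0], [0]], dtype=float)
        Y = np.array([0, 0, 1, 1], dtype=np.int8)  # cases carry nothing
        s = doestrare_statistic(X, Y, np.array([500]), 1_000)
        assert np.isfinite(s) and s >= 0

    def test_refined_grid_oracle(self):
        # single variant: statistic converges with grid refinement
        X = np.array([[2], [1], [0], [0], [0], [0]], dtype=float)
        Y = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        pos = np.array([400])
        coarse = doestrare_statistic(X, Y, pos, 1_000, bandwidth=50.0, grid_points=1_024)
        fine = doestrare_statistic(X, Y, pos, 1_000, bandwidth=50.0, grid_points=10_240)
        assert coarse == pytest.approx(fine, rel=1e-2)

    def test_binomial_weight_at_support_max_is_one(self):
        X = np.full((4, 1), 2.0)
        Y = np.array([1, 1, 0, 0], dtype=np.int8)
        pre = doestrare_precompute(X, Y, np.array([100]), 1_000)
        m1 = X.T @ Y.astype(float)
        w = stats.binom.cdf(m1, 2 * pre.n_cases, 0.5)
        assert w[0] == pytest.approx(1.0)


def test_statistics_row_permutation_invariant(rng):
    """All statistics are invariant to joint row permutations of (X, Y)."""
    X = (rng.random((24, 4)) < 0.2).astype(float) * rng.integers(1, 3, (24, 4))
    Y = np.array([1] * 12 + [0] * 12, dtype=np.int8)
    rng.shuffle(Y)
    pos = np.array([50, 200, 600, 900])
    mu = np.full(24, 0.5)
    perm = rng.permutation(24)
    Xp, Yp = X[perm], Y[perm]
    assert kbac_statistic(X, Y)[0] == pytest.approx(kbac_statistic(Xp, Yp)[0])
    assert doestrare_statistic(X, Y, pos, 1_000) == pytest.approx(
        doestrare_statistic(Xp, Yp, pos, 1_000)
    )
    k = podkat_kernel(pos, 1_000)
    assert podkat_Q(X, Y, mu, np.ones(4), k) == pytest.approx(
        podkat_Q(Xp, Yp, mu[perm], np.ones(4), k)
    )
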