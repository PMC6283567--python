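import itertools
import math

import numpy as np
import pytest
from scipy import stats

from rarestrat import (
    PermutationPlan,
    SeparationError,
    adaptive_permutation,
    fit_null,
    make_fixture,
    mixture_chisq_sf,
    run_test,
    score_test,
    skat_pvalue,
    skato_pvalue,
    stratified_permutation,
)
from rarestrat.inference import _make_stat_fn


class TestFitNull:
    def test_no_covariates_closed_form(self):
        y = np.array([1] * 6 + [0] * 4)
        null = fit_null(y)
        assert np.allclose(null.mu, 0.6)
        assert null.alpha[0] == pytest.approx(math.log(0.6 / 0.4))

    def test_score_equations_at_convergence(self, rng):
        n = 300
        Z = rng.normal(size=(n, 2))
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + Z @ [0.5, -0.8])))).astype(int)
        null = fit_null(y, Z)
        resid = y - null.mu
        assert np.max(np.abs(null.Z.T @ resid)) < 1e-8

    def test_separation_raises(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(SeparationError):
            fit_null(y, Z=y.astype(float))

    def test_constant_phenotype_errors(self):
        with pytest.raises(ValueError):
            fit_null(np.ones(5))


class TestScoreTest:
    def test_hand_fixture(self):
        fx = make_fixture("score_4")
        null = fit_null(fx["Y"])
        res = score_test(fx["S"], fx["Y"], null)
        assert res.U == pytest.approx(fx["U"])
        assert res.V == pytest.approx(fx["V"])
        assert res.Q == pytest.approx(fx["Q"])
        assert res.p == pytest.approx(stats.chi2.sf(3.0, 1), abs=1e-10)

    def test_constant_score_degenerate(self):
        y = np.array([1, 1, 0, 0])
        res = score_test(np.ones(4), y, fit_null(y))
        assert res.degenerate and res.p == 1.0

    def test_affine_invariance(self, rng):
        y = np.array([1] * 10 + [0] * 10)
        rng.shuffle(y)
        S = rng.normal(size=20)
        null = fit_null(y)
        q0 = score_test(S, y, null).Q
        q1 = score_test(3.7 * S + 2.0, y, null).Q
        assert q0 == pytest.approx(q1)

    def test_matches_wald_z_on_large_balanced_sample(self, rng):
        # asymptotic agreement with the squared Wald z of the logistic fit
        n = 2_000
        S = rng.binomial(2, 0.2, size=n).astype(float)
        logits = -0.2 + 0.25 * S
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        res = score_test(S, y, fit_null(y))
        import statsmodels.api as sm

        fit = sm.GLM(y, sm.add_constant(S), family=sm.families.Binomial()).fit()
        p_wald = fit.pvalues[1]
        assert res.p == pytest.approx(p_wald, rel=0.10)


class TestMixtureTail:
    def test_one_df_quantile(self):
        assert mixture_chisq_sf(np.array([1.0]), stats.chi2.isf(0.05, 1)) == pytest.approx(
            0.05, abs=1e-4
        )

    def test_scale_invariance(self):
        for c in (0.3, 2.0, 17.0):
            assert mixture_chisq_sf(np.array([c]), c * 3.0) == pytest.approx(
                mixture_chisq_sf(np.array([1.0]), 3.0), abs=1e-6
            )

    def test_two_df_closed_form(self):
        for q in (0.5, 2.0, 7.0):
            assert mixture_chisq_sf(np.array([1.0, 1.0]), q) == pytest.approx(
                math.exp(-q / 2.0), abs=1e-5
            )

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            mixture_chisq_sf(np.zeros(3), 1.0)


class TestSkatPvalues:
    def test_single_variant_matches_score_test(self, rng):
        n = 2_000
        x = rng.binomial(2, 0.01, size=(n, 1)).astype(float)
        y = np.array([1] * (n // 2) + [0] * (n // 2), dtype=np.int8)
        rng.shuffle(y)
        null = fit_null(y)
        p_skat, _ = skat_pvalue(x, y, null, np.ones(1), rho=0.0)
        p_score = score_test(x[:, 0], y, null).p
        assert p_skat == pytest.approx(p_score, abs=1e-4)

    def test_duplicated_column_halved_weights(self, rng):
        n = 400
        X = rng.binomial(2, 0.02, size=(n, 3)).astype(float)
        y = np.array([1] * (n // 2) + [0] * (n // 2), dtype=np.int8)
        rng.shuffle(y)
        null = fit_null(y)
        p0, q0 = skat_pvalue(X, y, null, np.ones(3), rho=0.0)
        Xd = np.column_stack([X, X])
        pd_, qd = skat_pvalue(Xd, y, null, np.full(6, 0.5), rho=0.0)
        # kernel algebra: duplicating columns with halved weights halves Q
        # and all eigenvalues, leaving the p-value unchanged
        assert pd_ == pytest.approx(p0, abs=1e-6)

    def test_skato_single_variant_equals_skat(self, rng):
        n = 300
        x = rng.binomial(2, 0.05, size=(n, 1)).astype(float)
        y = np.array([1] * 150 + [0] * 150, dtype=np.int8)
        rng.shuffle(y)
        null = fit_null(y)
        p_o, _ = skato_pvalue(x, y, null)
        p_s, _ = skat_pvalue(x, y, null, np.ones(1))
        assert p_o == pytest.approx(p_s, abs=1e-10)

    def test_skato_burden_signal_optimum_at_rho_one(self):
        # perfectly correlated variants aligned with the phenotype: the
        # burden end of the grid attains the minimum p
        from rarestrat.inference import (
            _half_kernel_eigenvalues,
            _perm_adjusted_Q,
            _rho_half_matrix,
        )
        from rarestrat import skat_Q

        n = 40
        X = np.zeros((n, 3))
        X[:12] = 1.0
        y = np.zeros(n, dtype=np.int8)
        y[:20] = 1
        null = fit_null(y)
        ps = []
        for r in [min(v, 0.999) for v in np.arange(0, 1.01, 0.1)]:
            B = X @ _rho_half_matrix(3, r)
            lam = _half_kernel_eigenvalues(B, null)
            q = skat_Q(X, y, null.mu, np.ones(3), r)
            ps.append(mixture_chisq_sf(lam, _perm_adjusted_Q(B, y, null, q, lam)))
        assert np.argmin(ps) == len(ps) - 1


class TestAdaptivePermutation:
    def test_boundary_p_values(self, rng):
        y = np.array([1] * 5 + [0] * 5, dtype=np.int8)
        plan = PermutationPlan(alpha=0.5, max_permutations=99, min_permutations=99)
        # statistic constant: every permutation ties the observed value
        p, m = adaptive_permutation(lambda v: 1.0, y, plan, rng)
        assert p == 1.0 and m == 99
        # observed strictly above everything achievable by permutation
        calls = iter([10.0] + [0.0] * 10_000)
        p, m = adaptive_permutation(lambda v: next(calls), y, plan, rng)
        assert p == pytest.approx(1.0 / (m + 1))

    def test_matches_exhaustive_enumeration_n6(self, rng):
        X = np.array([[2], [1], [0], [0], [0], [0]], dtype=np.int8)
        y = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        null = fit_null(y)
        stat = _make_stat_fn("kbac", X, null, None, None)
        s0 = stat(y)
        labels = {tuple(v) for v in itertools.permutations(y.tolist())}
        exact = np.mean(
            [stat(np.array(v, dtype=np.int8)) >= s0 - 1e-12 for v in labels]
        )
        plan = PermutationPlan(
            alpha=0.99, precision=0.03, max_permutations=20_000, min_permutations=200
        )
        p_hat, m = adaptive_permutation(stat, y, plan, rng)
        se = math.sqrt(exact * (1 - exact) / m)
        assert abs(p_hat - exact) <= 4 * se

    def test_two_budget_self_consistency(self, rng):
        X = (rng.random((30, 3)) < 0.2).astype(np.int8)
        y = np.array([1] * 15 + [0] * 15, dtype=np.int8)
        rng.shuffle(y)
        null = fit_null(y)
        stat = _make_stat_fn("kbac", X, null, None, None)
        c = 0.2
        plan_small = PermutationPlan(alpha=0.99, precision=c, max_permutations=500)
        plan_big = PermutationPlan(alpha=0.99, precision=0.05, max_permutations=20_000)
        p1, m1 = adaptive_permutation(stat, y, plan_small, rng)
        p2, m2 = adaptive_permutation(stat, y, plan_big, rng)
        assert abs(p1 - p2) <= 3 * c * max(p1, p2) + 0.05

    def test_nonfinite_statistic_errors(self, rng):
        y = np.array([1, 0, 1, 0], dtype=np.int8)
        with pytest.raises(ValueError):
            adaptive_permutation(lambda v: float("nan"), y, PermutationPlan(), rng)


class TestStratifiedPermutation:
    def test_case_count_conserved(self, rng):
        theta = np.exp(rng.normal(size=40))
        for _ in range(20):
            lab = stratified_permutation(theta, 13, rng)
            assert lab.sum() == 13

    def test_weighted_singleton_probability(self, rng):
        # N=3, n1=1, theta=(2,1,1): individual 1 is the case w.p. 0.5
        cnt = sum(
            int(stratified_permutation(np.array([2.0, 1.0, 1.0]), 1, rng)[0])
            for _ in range(4_000)
        )
        assert cnt / 4_000 == pytest.approx(0.5, abs=0.03)

    def test_uniform_theta_uniform_choice(self, rng):
        # chi-square goodness of fit of inclusion counts, N=6 choose 3
        counts = np.zeros(6)
        R = 4_000
        for _ in range(R):
            counts += stratified_permutation(np.ones(6), 3, rng)
        expected = R / 2.0
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=5) > 0.01


class TestCorrections:
    def _simulated_instance(self, rng, n=400):
        X = rng.binomial(2, 0.02, size=(n, 6)).astype(float)
        y = np.array([1] * (n // 2) + [0] * (n // 2), dtype=np.int8)
        rng.shuffle(y)
        return X, y

    def test_null_covariate_leaves_p_close(self, rng):
        X, y = self._simulated_instance(rng)
        Z = rng.normal(size=(len(y), 2))  # independent of X and Y
        p_unc = run_test("sum", X, y).p
        p_cor = run_test("sum", X, y, Z=Z, correction="pca_model").p
        assert p_cor == pytest.approx(p_unc, abs=0.05)

    def test_constant_covariate_aliased_with_intercept(self, rng):
        X, y = self._simulated_instance(rng)
        Z = rng.normal(size=(len(y), 1))
        p1 = run_test("skat", X, y, Z=Z, correction="pca_model").p
        Zc = np.column_stack([Z, np.ones(len(y))])
        p2 = run_test("skat", X, y, Z=Zc, correction="pca_model").p
        assert p2 == pytest.approx(p1, abs=1e-6)

    def test_model_correction_rejects_nonregression_methods(self, rng):
        X, y = self._simulated_instance(rng)
        Z = rng.normal(size=(len(y), 2))
        for method in ("kbac", "doestrare", "wsum_mafctrl", "asum"):
            with pytest.raises(ValueError):
                run_test(
                    method, X, y, positions=np.arange(1, 7) * 100.0,
                    gene_length=1_000.0, Z=Z, correction="pca_model",
                )

    def test_separation_raises_at_full_confounding(self):
        y = np.array([1] * 20 + [0] * 20, dtype=np.int8)
        Z = y.astype(float)[:, None]
        X = np.zeros((40, 2))
        X[::3] = 1
        with pytest.raises(SeparationError):
            run_test("sum", X, y, Z=Z, correction="pca_model")

    def test_perm_correction_without_covariates_is_plain(self, rng):
        X, y = self._simulated_instance(rng, n=60)
        res = run_test(
            "kbac", X, y, correction="none",
            plan=PermutationPlan(max_permutations=200), rng=rng,
        )
        assert 0.0 < res.p <= 1.0
        assert res.permutations > 0

    def test_perm_correction_preserves_case_count(self, rng):
        n = 80
        X, y = self._simulated_instance(rng, n=n)
        Z = rng.normal(size=(n, 1)) + 0.5 * y[:, None]
        res = run_test(
            "kbac", X, y, Z=Z, correction="pca_perm",
            plan=PermutationPlan(max_permutations=100), rng=rng,
        )
        assert 0.0 < res.p <= 1.0


def test_analytic_vs_permutation_cross_oracle(rng):
    """Analytic kernel p-values match plain permutation within Monte-Carlo
    error on small instances (the cross-method oracle)."""
    from rarestrat import podkat_kernel, skat_Q
    from rarestrat.inference import podkat_pvalue

    N, P = 18, 4
    for _ in range(3):
        X = np.clip(rng.integers(0, 2, (N, P)) + rng.integers(0, 2, (N, P)), 0, 2)
        y = np.zeros(N, dtype=np.int8)
        y[: N // 2] = 1
        rng.shuffle(y)
        null = fit_null(y)
        p_an, Q = skat_pvalue(X, y, null, np.ones(P), rho=0.0)
        M = 500
        perms = np.array(
            [skat_Q(X, rng.permutation(y), null.mu, np.ones(P), 0.0) for _ in range(M)]
        )
        p_perm = ((perms >= Q - 1e-12).sum() + 1) / (M + 1)
        se = math.sqrt(p_perm * (1 - p_perm) / M)
        assert abs(p_an - p_perm) <= 3 * se + 1e-9
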