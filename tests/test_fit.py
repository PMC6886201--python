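"""The l0 joint fit: closed-form solutions, keep/kill rule, global delta
search, normalization recovery, and optimality against brute-force oracles."""

import numpy as np
import pytest

from jointde import (
    ValidationError,
    center_data,
    fit_type1,
    fit_type2,
    beta_p_ols,
    ols_betas,
    optimize_delta_type1,
    recover_normalization,
    type1_delta_objective,
    type1_keep_rule,
    type2_keep_rule,
    weighted_beta_mean,
)
from jointde._linalg import ols_coefficients, project_out
from oracles import (
    direct_objective_type1,
    enumerate_type1_optimum,
    enumerate_type2_optimum,
)


def random_instance(seed, m=6, n=8, p=1, signal=True):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    beta = np.zeros((m, p))
    if signal:
        k = int(rng.integers(1, m + 1))
        beta[rng.permutation(m)[:k]] = rng.normal(0, 2, size=(k, p))
    y = (rng.standard_normal(m)[:, None] + beta @ x.T
         + rng.standard_normal(n)[None, :]
         + 0.4 * rng.standard_normal((m, n)))
    var = rng.uniform(0.1, 1.0, size=m)
    return y, x, var


# ---------------------------------------------------------------------------
# unit-level behaviour
# ---------------------------------------------------------------------------

class TestOlsBetas:
    def test_zero_response_gives_delta(self):
        y, x, var = random_instance(0, signal=False)
        cd = center_data(y, x, var)
        cd.y_tilde[:] = 0.0
        np.testing.assert_allclose(ols_betas(cd, [0.0]), 0.0)
        np.testing.assert_allclose(ols_betas(cd, [1.3]), 1.3)

    def test_exact_slope(self):
        y = np.zeros((2, 3))
        x = np.array([[-1.0], [0.0], [1.0]])
        cd = center_data(y, x, np.ones(2))
        cd.y_tilde[:] = np.array([-2.0, 0.0, 2.0])  # already-centered response
        out = ols_betas(cd, [0.0])
        np.testing.assert_allclose(out, 2.0, atol=1e-12)

    def test_matches_grid_search_oracle(self):
        y, x, var = random_instance(4, m=3, p=1)
        cd = center_data(y, x, var)
        out = ols_betas(cd, [0.0])
        grid = np.linspace(-6, 6, 200001)
        for i in range(3):
            sse = ((cd.y_tilde[i][:, None] - cd.x_tilde @ grid[None, :]) ** 2).sum(axis=0)
            assert abs(out[i, 0] - grid[np.argmin(sse)]) < 1e-4


class TestType1KeepRule:
    def test_lambda_extremes(self):
        y, x, var = random_instance(1)
        cd = center_data(y, x, var)
        sel0, beta0 = type1_keep_rule(cd, var, np.zeros(cd.m), [0.0])
        assert sel0.all()
        sel_inf, beta_inf = type1_keep_rule(cd, var, np.full(cd.m, np.inf), [0.0])
        assert not sel_inf.any()
        np.testing.assert_array_equal(beta_inf, 0.0)

    def test_tie_keeps_gene(self):
        # statistic exactly equal to lambda -> kept (kill only on strict <)
        y, x, var = random_instance(2, m=2)
        cd = center_data(y, x, var)
        bols = ols_betas(cd, [0.0])
        fitted = cd.x_tilde @ bols.T
        stat = (fitted**2).sum(axis=0) / (2 * var)
        sel, _ = type1_keep_rule(cd, var, stat, [0.0])
        assert sel.all()


class TestDeltaObjective:
    def test_zero_data_zero_objective(self):
        y, x, var = random_instance(3, signal=False)
        cd = center_data(y, x, var)
        cd.y_tilde[:] = 0.0
        assert type1_delta_objective(cd, var, np.full(cd.m, 2.0), [0.0]) == 0.0

    def test_matches_term_by_term_loop(self):
        y, x, var = random_instance(6, m=20)
        cd = center_data(y, x, var)
        lam = np.random.default_rng(0).uniform(0, 3, size=20)
        for delta in np.random.default_rng(1).uniform(-4, 4, size=50):
            total = 0.0
            for i in range(20):
                bi = ols_betas(cd, [delta])[i]
                total += min((cd.x_tilde @ bi) @ (cd.x_tilde @ bi) / (2 * var[i]),
                             lam[i])
            got = type1_delta_objective(cd, var, lam, [delta])
            assert got == pytest.approx(total, rel=1e-10)

    def test_unpenalized_minimizer_is_weighted_mean(self):
        y, x, var = random_instance(7, m=10)
        cd = center_data(y, x, var)
        lam = np.full(10, np.inf)
        delta = optimize_delta_type1(cd, var, lam)
        b = ols_coefficients(cd.x_tilde, cd.y_tilde)[:, 0]
        wts = (cd.x_tilde[:, 0] ** 2).sum() / var
        expected = -(wts * b).sum() / wts.sum()
        assert delta[0] == pytest.approx(expected, abs=1e-8)


class TestOptimizeDelta:
    def test_single_gene_infinite_lambda(self):
        y, x, var = random_instance(8, m=1)
        cd = center_data(y, x, var)
        delta = optimize_delta_type1(cd, var, np.array([np.inf]))
        b = ols_coefficients(cd.x_tilde, cd.y_tilde)[0, 0]
        assert delta[0] == pytest.approx(-b, abs=1e-8)

    def test_flat_objective_tie_breaks_to_zero(self):
        y, x, var = random_instance(9)
        cd = center_data(y, x, var)
        delta = optimize_delta_type1(cd, var, np.zeros(cd.m))
        np.testing.assert_array_equal(delta, 0.0)

    def test_beats_dense_brute_force_grid(self):
        y, x, var = random_instance(10, m=50)
        cd = center_data(y, x, var)
        lam = np.random.default_rng(2).uniform(0.1, 4.0, size=50)
        delta = optimize_delta_type1(cd, var, lam)
        found = type1_delta_objective(cd, var, lam, delta)
        b = ols_coefficients(cd.x_tilde, cd.y_tilde)[:, 0]
        a = (cd.x_tilde[:, 0] ** 2).sum() / (2 * var)
        grid = np.linspace(-b.max() - 1, -b.min() + 1, 1_000_000)
        vals_min = np.inf
        for start in range(0, grid.size, 100_000):
            g = grid[start:start + 100_000]
            vals = np.minimum(a[:, None] * (b[:, None] + g[None, :]) ** 2,
                              lam[:, None]).sum(axis=0)
            vals_min = min(vals_min, vals.min())
        assert found <= vals_min + 1e-6 * abs(vals_min)


class TestRecoverNormalization:
    def test_null_beta_closed_form(self):
        y, x, var = random_instance(11)
        cd = center_data(y, x, var)
        d, alpha = recover_normalization(cd, np.zeros((cd.m, cd.p)))
        np.testing.assert_allclose(
            d, cd.weighted_col_means - cd.weighted_col_means[0], atol=1e-12)
        np.testing.assert_allclose(
            alpha,
            cd.row_means + cd.weighted_col_means[0] - cd.grand_weighted_mean,
            atol=1e-12)

    def test_alpha_plus_d_identity(self):
        """alpha_i + d_j matches the stationarity closed form at every cell."""
        y, x, var = random_instance(12)
        cd = center_data(y, x, var)
        beta = np.random.default_rng(3).standard_normal((cd.m, cd.p))
        d, alpha = recover_normalization(cd, beta)
        bbar = weighted_beta_mean(beta, var)
        for i in range(cd.m):
            for j in range(cd.n):
                expected = (cd.row_means[i] + cd.weighted_col_means[j]
                            - cd.grand_weighted_mean
                            - cd.x_tilde[j] @ bbar
                            - cd.covariate_means @ beta[i])
                assert alpha[i] + d[j] == pytest.approx(expected, abs=1e-10)

    def test_location_equivariance(self):
        y, x, var = random_instance(13)
        fit_a = fit_type1(y, x, var, 1.0)
        fit_b = fit_type1(y + 3.7, x, var, 1.0)
        np.testing.assert_allclose(fit_b.d, fit_a.d, atol=1e-8)
        np.testing.assert_allclose(fit_b.alpha, fit_a.alpha + 3.7, atol=1e-8)


class TestFitType1:
    def test_null_data_kills_everything(self):
        y, x, var = random_instance(14, signal=False)
        # make ytilde exactly zero: y is pure row+column structure
        rng = np.random.default_rng(0)
        y = rng.standard_normal(6)[:, None] + rng.standard_normal(8)[None, :]
        fit = fit_type1(y, x, np.ones(6), 2.0)
        assert not fit.selected.any()
        assert abs(fit.delta_opt[0]) < 1e-12
        cd = center_data(y, x, np.ones(6))
        np.testing.assert_allclose(
            fit.d, cd.weighted_col_means - cd.weighted_col_means[0], atol=1e-8)

    def test_objective_equals_direct_evaluation(self):
        y, x, var = random_instance(15)
        lam = 1.5
        fit = fit_type1(y, x, var, lam)
        cd = center_data(y, x, var)
        direct = direct_objective_type1(cd, var, np.full(cd.m, lam),
                                        fit.beta, fit.delta_opt)
        assert fit.objective == pytest.approx(direct, rel=1e-8)
        assert fit.d[0] == 0.0

    def test_monotone_sparsity_in_lambda(self):
        y, x, var = random_instance(16, m=30)
        counts = []
        for lam in [0.0, 0.3, 1.0, 3.0, 10.0, 1e3]:
            counts.append(fit_type1(y, x, var, lam).selected.sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        y, x, var = random_instance(seed, m=6, n=8, p=1)
        lam = np.random.default_rng(seed).uniform(0.2, 3.0, size=6)
        fit = fit_type1(y, x, var, lam)
        cd = center_data(y, x, var)
        best = enumerate_type1_optimum(cd, var, lam)
        assert fit.objective == pytest.approx(best, rel=1e-6)


class TestType2:
    def test_beta_p_reduces_to_full_ols_at_p1(self):
        y, x, var = random_instance(17, p=1)
        cd = center_data(y, x, var)
        np.testing.assert_allclose(beta_p_ols(cd, 0.4),
                                   ols_betas(cd, [0.4])[:, 0], rtol=1e-10)

    def test_beta_p_matches_full_ols_coordinate(self):
        """Partitioned form equals the last coordinate of the joint OLS fit
        (Frisch-Waugh consistency) at p = 2."""
        y, x, var = random_instance(18, p=2)
        cd = center_data(y, x, var)
        full = ols_coefficients(cd.x_tilde, cd.y_tilde)
        np.testing.assert_allclose(beta_p_ols(cd, 0.0), full[:, -1], rtol=1e-8)
        np.testing.assert_allclose(beta_p_ols(cd, 0.9), full[:, -1] + 0.9,
                                   rtol=1e-8)

    def test_keep_rule_extremes(self):
        y, x, var = random_instance(19, p=2)
        cd = center_data(y, x, var)
        sel, beta = type2_keep_rule(cd, var, np.zeros(cd.m), 0.0)
        assert sel.all()
        sel, beta = type2_keep_rule(cd, var, np.full(cd.m, np.inf), 0.0)
        assert not sel.any()
        assert np.all(beta[:, -1] == 0.0)
        # reduced-model coordinates match OLS on the adjustment covariates
        red = ols_coefficients(cd.x_tilde[:, :-1], cd.y_tilde)
        np.testing.assert_allclose(beta[:, :-1], red, rtol=1e-8)

    def test_objective_gap_matches_direct_evaluation(self):
        """The keep/kill statistic equals the reduced-vs-full objective drop
        evaluated literally at both coefficient vectors."""
        y, x, var = random_instance(20, m=4, p=2)
        cd = center_data(y, x, var)
        delta_p = 0.7
        delta = np.array([0.0, delta_p])
        full = ols_betas(cd, delta)
        xp_res = project_out(cd.x_tilde[:, :-1], cd.x_tilde[:, -1][None, :])[0]
        s = xp_res @ xp_res
        bp = (cd.y_tilde @ xp_res) / s + delta_p
        red = np.zeros_like(full)
        red[:, :-1] = ols_coefficients(
            cd.x_tilde[:, :-1],
            cd.y_tilde + np.outer(np.ones(cd.m), cd.x_tilde[:, -1]) * delta_p)
        for i in range(cd.m):
            h = lambda b: ((cd.y_tilde[i] + cd.x_tilde @ delta
                            - cd.x_tilde @ b) ** 2).sum() / (2 * var[i])
            gap = h(red[i]) - h(full[i])
            stat = s * bp[i] ** 2 / (2 * var[i])
            assert gap == pytest.approx(stat, rel=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration_p2(self, seed):
        y, x, var = random_instance(100 + seed, m=5, n=8, p=2)
        lam = np.random.default_rng(seed).uniform(0.2, 3.0, size=5)
        fit = fit_type2(y, x, var, lam)
        cd = center_data(y, x, var)
        best = enumerate_type2_optimum(cd, var, lam)
        assert fit.objective == pytest.approx(best, rel=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_coincides_with_type1_at_p1(self, seed):
        y, x, var = random_instance(200 + seed, m=15, p=1)
        lam = 1.8
        f1 = fit_type1(y, x, var, lam)
        f2 = fit_type2(y, x, var, lam)
        np.testing.assert_array_equal(f1.selected, f2.selected)
        # the two 1-D refinements agree to the optimizer's sqrt(eps) floor
        np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(f1.d, f2.d, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(f1.alpha, f2.alpha, rtol=1e-6, atol=1e-8)


class TestEquivalences:
    def test_equal_variance_scaling_equivalence(self):
        """With all sigma_i^2 equal to v, fitting with (var=v, lambda) equals
        fitting with (var=1, lambda*v): the noise scale can be folded into
        the tuning parameter."""
        y, x, _ = random_instance(30, m=10)
        v = 0.37
        lam = 1.1
        f_scaled = fit_type1(y, x, np.full(10, v), lam)
        f_unit = fit_type1(y, x, np.ones(10), lam * v)
        np.testing.assert_array_equal(f_scaled.selected, f_unit.selected)
        np.testing.assert_allclose(f_scaled.beta, f_unit.beta, rtol=1e-8,
                                   atol=1e-12)
        np.testing.assert_allclose(f_scaled.d, f_unit.d, rtol=1e-8, atol=1e-12)

    def test_rejects_empty_input(self):
        with pytest.raises(ValidationError):
            optimize_delta_type1(
                center_data(np.zeros((0, 3)), np.arange(3.0)[:, None],
                            np.zeros(0)),
                np.zeros(0), np.zeros(0))
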