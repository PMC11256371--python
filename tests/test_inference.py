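"""The penalized-fit and debiasing engine against closed forms, the OLS
limit, and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from dustdab.inference import (check_kkt, choose_lambda, cv_fit,
                               debias_and_test, fit_lasso, lambda_grid,
                               lambda_max, nodewise_theta, residualize,
                               run_differential_abundance)
from dustdab.studies import _design_from_matrix, gaussian_design
from dustdab import (SimConfig, simulate_counts, simulate_covariates,
                     simulate_outcomes)


def _toy_design(n=80, p=10, s=3, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = gaussian_design(n, p, seed=seed)
    beta = np.zeros(p)
    beta[:s] = [0.8, -0.5, 0.4][:s]
    y = X @ beta + rng.normal(0, noise, n)
    return _design_from_matrix(X, y), beta


class TestFitLasso:
    def test_lambda_above_max_gives_zero(self):
        design, _ = _toy_design()
        Xt, yt, _ = residualize(design)
        lam = lambda_max(Xt, yt)
        fit = fit_lasso(design, lam * 1.0001)
        assert np.all(fit.beta == 0)

    def test_lambda_zero_equals_ols(self):
        design, _ = _toy_design(n=120, p=15)
        fit = fit_lasso(design, 0.0)
        Xt, yt, _ = residualize(design)
        ols = np.linalg.lstsq(Xt, yt, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-6)

    def test_orthonormal_soft_threshold(self):
        rng = np.random.default_rng(1)
        n, p = 64, 8
        M = rng.standard_normal((n, p))
        M -= M.mean(axis=0)  # centered inputs => centered orthonormal basis
        Q, _ = np.linalg.qr(M)
        X = Q * np.sqrt(n)  # columns with x_j^T x_j = n
        y = rng.standard_normal(n)
        design = _design_from_matrix(X, y - y.mean())
        lam = 0.11
        fit = fit_lasso(design, lam)
        Xt, yt, _ = residualize(design)
        target = Xt.T @ yt / n
        expect = np.sign(target) * np.maximum(np.abs(target) - lam, 0)
        assert np.allclose(fit.beta, expect, atol=1e-6)

    def test_kkt_conditions_hold(self):
        design, _ = _toy_design(n=100, p=30, seed=3)
        Xt, yt, _ = residualize(design)
        for lam in (0.01, 0.05, 0.2):
            fit = fit_lasso(design, lam)
            assert check_kkt(Xt, yt, fit.beta, lam)

    def test_negative_lambda_rejected(self):
        design, _ = _toy_design()
        with pytest.raises(ValueError):
            fit_lasso(design, -0.1)


class TestChooseLambda:
    def test_grid_spans_three_decades_from_max(self):
        g = lambda_grid(1.0)
        assert len(g) == 100 and np.isclose(g[0], 1.0) \
            and np.isclose(g[-1], 1e-3)

    def test_same_seed_same_lambda(self):
        design, _ = _toy_design(n=100, p=20, seed=5)
        l1, _ = choose_lambda(design, seed=11)
        l2, _ = choose_lambda(design, seed=11)
        assert l1 == l2

    def test_pure_noise_selects_near_lambda_max(self):
        # under the global null the CV curve is minimized at the top of the
        # grid: the chosen penalty stays within a factor 2 of lambda_max in
        # >= 80% of replicates and its median index is the very top
        hits = 0
        reps = 50
        indices = []
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            X = gaussian_design(100, 20, seed=200 + r)
            y = rng.standard_normal(100)
            design = _design_from_matrix(X, y - y.mean())
            lam, info = choose_lambda(design, seed=r, n_points=30)
            indices.append(info["best_index"])
            if lam >= info["grid"][0] / 2:
                hits += 1
        assert hits / reps >= 0.8
        assert np.median(indices) == 0

    def test_strong_signal_low_noise_selects_small_lambda(self):
        design, _ = _toy_design(n=200, p=10, s=1, seed=7, noise=1e-4)
        lam, info = choose_lambda(design, seed=0)
        grid = info["grid"]
        assert lam <= grid[0] * 10 ** (-2)  # in the lowest decade


class TestNodewise:
    def test_orthonormal_theta_is_identity(self):
        rng = np.random.default_rng(2)
        n, p = 100, 6
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)
        Theta, tau = nodewise_theta(X, lambda_node=0.0)
        assert np.allclose(Theta, np.eye(p), atol=1e-8)
        assert np.allclose(tau, 1.0, atol=1e-8)

    def test_two_column_inverse_oracle(self):
        rho = 0.6
        rng = np.random.default_rng(3)
        n = 200_00
        X = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        Theta, _ = nodewise_theta(X, lambda_node=0.0)
        Sigma = X.T @ X / n
        assert np.allclose(Theta, np.linalg.inv(Sigma), atol=1e-6)

    def test_kkt_bound_on_theta_sigma(self):
        X = gaussian_design(150, 30, rho=0.4, seed=4)
        lam = 0.08
        Theta, tau = nodewise_theta(X, lambda_node=lam)
        Sigma = X.T @ X / X.shape[0]
        dev = np.abs(Theta @ Sigma - np.eye(30))
        bound = (lam / tau ** 2)[:, None]
        assert np.all(dev <= bound + 1e-6)

    def test_collinear_columns_error(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        X = np.column_stack([x, x, rng.standard_normal(50)])
        from dustdab.inference import CollinearityError
        with pytest.raises(CollinearityError):
            nodewise_theta(X, lambda_node=0.0)


class TestDebias:
    def test_ols_limit_identity(self):
        rng = np.random.default_rng(6)
        n, p = 200, 20
        X = gaussian_design(n, p, seed=6)
        y = X[:, 0] * 0.4 + rng.standard_normal(n)
        design = _design_from_matrix(X, y - y.mean())
        Xt, yt, _ = residualize(design)
        fit = fit_lasso(design, 0.0)
        Theta, _ = nodewise_theta(Xt, lambda_node=0.0)
        res = debias_and_test(fit, Theta, Xt, yt)

        A = np.column_stack([np.ones(n), X])
        bh = np.linalg.lstsq(A, y, rcond=None)[0]
        r = y - A @ bh
        s2 = r @ r / (n - p - 1)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(A.T @ A)))[1:]
        assert np.allclose(res.b, bh[1:], atol=1e-8)
        assert np.allclose(res.se, se, atol=1e-8)

    def test_scale_equivariance(self):
        design, _ = _toy_design(n=150, p=25, seed=8)
        Xt, yt, _ = residualize(design)
        Theta, _ = nodewise_theta(Xt, lambda_node=0.05)
        fit = fit_lasso(design, 0.07)
        res1 = debias_and_test(fit, Theta, Xt, yt)
        c = 3.7
        design2 = _design_from_matrix(design.X, design.y * c)
        fit2 = fit_lasso(design2, 0.07 * c)
        res2 = debias_and_test(fit2, Theta, Xt, yt * c)
        assert np.allclose(res2.b, c * res1.b, atol=1e-8)
        assert np.allclose(res2.se, c * res1.se, atol=1e-8)
        assert np.allclose(res2.z, res1.z, atol=1e-8)
        assert np.allclose(res2.p_values, res1.p_values, atol=1e-10)

    def test_column_order_invariance(self):
        design, _ = _toy_design(n=120, p=12, seed=9)
        perm = np.random.default_rng(9).permutation(12)
        design2 = _design_from_matrix(design.X[:, perm], design.y)
        for d in (design, design2):
            Xt, yt, _ = residualize(d)
            Theta, _ = nodewise_theta(Xt, lambda_node=0.04)
            d.res = debias_and_test(fit_lasso(d, 0.06), Theta, Xt, yt)
        assert np.allclose(design2.res.b, design.res.b[perm], atol=1e-8)
        assert np.allclose(design2.res.p_values, design.res.p_values[perm],
                           atol=1e-10)

    def test_negative_df_errors(self):
        design, _ = _toy_design(n=20, p=25, seed=10)
        fit = fit_lasso(design, 0.05)
        fit.beta[:] = 1.0  # force full support so df = n - s - 1 < 0
        Xt, yt, _ = residualize(design)
        with pytest.raises(ValueError, match="df"):
            debias_and_test(fit, np.eye(25), Xt, yt)


@pytest.fixture(scope="module")
def sim():
    cfg = SimConfig(n_samples=400, n_taxa=100, n_causal=3,
                    effect_sizes=[0.4, -0.4, 0.4], seed=21)
    table = simulate_counts(cfg)
    covars = simulate_covariates(cfg.n_samples, seed=cfg.seed)
    frame, truth = simulate_outcomes(table, covars, cfg, outcome="fev1")
    return table, frame, truth


class TestPipeline:
    def test_planted_taxa_recovered_with_few_false_positives(self, sim):
        table, frame, truth = sim
        res = run_differential_abundance(table, frame, "fev1", seed=13)
        sig = set(res.significant_taxa())
        assert set(truth.causal_taxon_ids) <= sig
        # false positives near the nominal level: expect ~0.05 * p
        assert len(sig - set(truth.causal_taxon_ids)) <= 15

    def test_same_seed_identical_results(self, sim):
        table, frame, _ = sim
        r1 = run_differential_abundance(table, frame, "fev1", seed=13)
        r2 = run_differential_abundance(table, frame, "fev1", seed=13)
        pd.testing.assert_frame_equal(r1.data, r2.data)

    def test_signs_match_planted_effects(self, sim):
        table, frame, truth = sim
        res = run_differential_abundance(table, frame, "fev1", seed=13)
        d = res.data.set_index("taxon_id")
        for tid in truth.causal_taxon_ids:
            j = truth.taxon_ids.index(tid)
            assert np.sign(d.loc[tid, "coefficient"]) == \
                np.sign(truth.true_beta[j])
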