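"""Network autocorrelation model: likelihood, fitting, and simulation."""

import numpy as np
import pytest
import statsmodels.api as sm

from affilex import (
    DesignError,
    SingularityError,
    admissible_interval,
    affiliation_exposure,
    fit_nam,
    nam_loglik,
    row_normalize,
    simulate_nam,
)
from affilex.nam import log_det_term, profile_fit, w_eigenvalues, _design
from affilex.synth import GeneratorConfig, generate_recovery_instance


def random_w(rng, n=8):
    """Row-normalized projection of a random binary two-mode matrix."""
    A = rng.integers(0, 2, size=(n, 4))
    A[0, 0] = 1  # avoid the fully isolated degenerate draw
    return row_normalize(A @ A.T)


@pytest.fixture
def instance():
    return generate_recovery_instance(GeneratorConfig(seed=11, n_users=120))


class TestRowNormalize:
    def test_hand_example(self):
        C = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 2]])
        W = row_normalize(C).W
        assert W.tolist() == [[0, 0, 1], [0, 0, 1], [0.5, 0.5, 0]]

    def test_wy_equals_exposure(self, rng):
        A = rng.integers(0, 2, size=(10, 5))
        C = A @ A.T
        y = rng.normal(size=10)
        W = row_normalize(C)
        F = affiliation_exposure(C, y).to_numpy()
        ok = np.abs(W.W).sum(axis=1) > 0
        assert np.allclose((W.W @ y)[ok], F[ok], atol=1e-12)

    def test_equal_offdiagonals_give_uniform_rows(self):
        C = np.full((4, 4), 3)
        np.fill_diagonal(C, 5)
        W = row_normalize(C).W
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(W[off], 1 / 3)
        assert np.all(np.diag(W) == 0)

    def test_isolate_rows_stay_zero(self):
        C = np.diag([2, 3])
        assert row_normalize(C).W.tolist() == [[0, 0], [0, 0]]


class TestLoglik:
    def test_rho_zero_matches_ols_gaussian_loglik(self, rng):
        n = 40
        W = random_w(rng, n=10).W
        W = np.kron(np.eye(4), W)  # n=40 block W; content irrelevant at rho=0
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        D = rng.integers(0, 5, size=n).astype(float)
        y = rng.normal(size=n) * 2 + X @ [1.0, 0.5] + 0.3 * D
        M = np.column_stack([X, D])
        ols = sm.OLS(y, M).fit()
        beta = ols.params[:2]
        gamma = ols.params[2]
        sigma2 = float(ols.resid @ ols.resid) / n
        ll = nam_loglik(0.0, beta, gamma, sigma2, y, W, X, D)
        assert np.isclose(ll, ols.llf, atol=1e-8)

    def test_log_determinant_matches_dense_oracle(self, rng):
        for _ in range(5):
            W = random_w(rng, n=8).W
            lam = w_eigenvalues(W)
            lo, hi = admissible_interval(W, lam)
            lo, hi = max(lo, -3.0), min(hi, 3.0)
            pad = 0.025 * (hi - lo)
            for rho in np.linspace(lo + pad, hi - pad, 25):
                direct = np.linalg.slogdet(np.eye(8) - rho * W)[1]
                assert abs(log_det_term(rho, lam) - direct) < 1e-9

    def test_rho_outside_interval_rejected(self, rng):
        W = random_w(rng)
        lo, hi = admissible_interval(W, delta=0.0)
        n = W.W.shape[0]
        X = np.ones((n, 1))
        D = np.zeros(n)
        with pytest.raises(SingularityError):
            nam_loglik(hi + 0.5, [0.0], 0.0, 1.0, np.zeros(n), W, X, D)

    def test_noise_free_limit_maximized_at_truth(self, rng):
        inst = generate_recovery_instance(GeneratorConfig(seed=3, n_users=60))
        # regenerate outcome without noise at the known parameters
        t = inst.truth
        y0 = simulate_nam(
            inst.weight, inst.X.to_numpy(), inst.D,
            rho=t["rho"], beta=t["beta"], gamma=t["gamma"], sigma=0.0, seed=1,
        )
        M = np.column_stack([inst.X.to_numpy(), inst.D])
        lam = w_eigenvalues(inst.weight)
        theta, sigma2, _ = profile_fit(t["rho"], y0, inst.weight, M, lam)
        assert np.allclose(theta, t["beta"] + [t["gamma"]], atol=1e-8)
        assert sigma2 < 1e-16  # residual term vanishes


class TestFit:
    def test_reduces_to_ols_at_fixed_rho_zero(self, instance):
        M = np.column_stack([instance.X.to_numpy(), instance.D])
        ols = np.linalg.lstsq(M, instance.y, rcond=None)[0]
        fit = fit_nam(instance.y, instance.weight, instance.X.to_numpy(),
                      instance.D, rho=0.0)
        assert np.allclose(fit.coef["estimate"].to_numpy(), ols, atol=1e-10)
        assert fit.rho == 0.0

    def test_free_fit_beats_ols_loglik_and_stays_in_interval(self, instance):
        free = fit_nam(instance.y, instance.weight, instance.X.to_numpy(), instance.D)
        fixed = fit_nam(instance.y, instance.weight, instance.X.to_numpy(),
                        instance.D, rho=0.0)
        assert free.loglik >= fixed.loglik - 1e-9
        lo, hi = free.rho_interval
        assert lo < free.rho < hi

    def test_profile_maximizer_agrees_with_grid_search(self, instance):
        fit = fit_nam(instance.y, instance.weight, instance.X.to_numpy(), instance.D)
        M = np.column_stack([instance.X.to_numpy(), instance.D])
        lam = w_eigenvalues(instance.weight)
        lo, hi = fit.rho_interval
        grid = np.arange(max(lo, -2.0), hi, 1e-3)
        lls = [profile_fit(r, instance.y, instance.weight, M, lam)[2] for r in grid]
        assert abs(grid[int(np.argmax(lls))] - fit.rho) <= 1e-3

    def test_recovers_generating_parameters_roughly(self, instance):
        fit = fit_nam(instance.y, instance.weight, instance.X.to_numpy(),
                      instance.D, names=list(instance.X.columns))
        t = instance.truth
        assert abs(fit.rho - t["rho"]) < 4 * fit.rho_se + 0.05
        assert abs(fit.gamma - t["gamma"]) < 0.5

    def test_bias_shrinks_with_sample_size(self):
        """Mean absolute rho error decreases from n=100 to n=1000."""
        errs = {}
        for n in (100, 300, 1000):
            e = []
            for s in range(8):
                inst = generate_recovery_instance(
                    GeneratorConfig(seed=500 + s, n_users=n)
                )
                f = fit_nam(inst.y, inst.weight, inst.X.to_numpy(), inst.D)
                e.append(abs(f.rho - inst.truth["rho"]))
            errs[n] = np.mean(e)
        assert errs[1000] < errs[100]

    def test_omitting_degree_control_shifts_estimates(self):
        """D is a real confounder: dropping it moves the fitted coefficients."""
        inst = generate_recovery_instance(GeneratorConfig(seed=21, n_users=150))
        with_d = fit_nam(inst.y, inst.weight, inst.X.to_numpy(), inst.D)
        without_d = fit_nam(inst.y, inst.weight, inst.X.to_numpy(), None)
        assert abs(with_d.rho - without_d.rho) > 1e-3
        assert "sas_affiliated" not in without_d.coef.index

    def test_rank_deficient_design_named(self, instance):
        X = instance.X.to_numpy()
        X = np.column_stack([X, X[:, 1]])  # duplicate the medication column
        with pytest.raises(DesignError, match="rank"):
            fit_nam(instance.y, instance.weight, X, instance.D,
                    names=["intercept", "medication", "diagnosis", "lifestyle", "dup"])

    def test_design_helper_appends_degree_column(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        M, names = _design(X, rng.normal(size=10), ["intercept", "z"])
        assert names == ["intercept", "z", "sas_affiliated"]
        assert M.shape == (10, 3)


class TestSimulate:
    def test_zero_rho_zero_noise_is_linear_predictor(self, rng):
        W = random_w(rng)
        n = W.W.shape[0]
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        D = rng.integers(0, 4, size=n).astype(float)
        y = simulate_nam(W, X, D, rho=0.0, beta=[2.0, -1.0], gamma=0.5,
                         sigma=0.0, seed=4)
        assert np.allclose(y, X @ [2.0, -1.0] + 0.5 * D)

    def test_deterministic_given_seed(self, rng):
        W = random_w(rng)
        n = W.W.shape[0]
        X = np.ones((n, 1))
        D = np.zeros(n)
        a = simulate_nam(W, X, D, 0.3, [1.0], 0.0, 2.0, seed=9)
        b = simulate_nam(W, X, D, 0.3, [1.0], 0.0, 2.0, seed=9)
        assert np.array_equal(a, b)

    def test_rho_at_endpoint_rejected(self, rng):
        W = random_w(rng)
        n = W.W.shape[0]
        _, hi = admissible_interval(W, delta=0.0)
        with pytest.raises(SingularityError):
            simulate_nam(W, np.ones((n, 1)), np.zeros(n), hi, [0.0], 0.0, 1.0, seed=1)

    def test_moments_match_closed_form_on_five_nodes(self):
        rng = np.random.default_rng(77)
        A = np.array([[1, 0], [1, 1], [0, 1], [1, 0], [1, 1]])
        W = row_normalize(A @ A.T)
        n = 5
        X = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        D = A.sum(axis=1).astype(float)
        rho, beta, gamma, sigma = 0.4, [1.0, 0.3], 0.2, 1.5
        inv = np.linalg.inv(np.eye(n) - rho * W.W)
        mean_true = inv @ (X @ beta + gamma * D)
        cov_true = sigma**2 * inv @ inv.T
        draws = np.array([
            simulate_nam(W, X, D, rho, beta, gamma, sigma, seed=rng)
            for _ in range(4000)
        ])
        assert np.allclose(draws.mean(axis=0), mean_true, atol=0.12)
        assert np.allclose(np.cov(draws.T), cov_true, atol=0.25)
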