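import numpy as np
import pytest

from paom import (
    ConfigurationError,
    FitOptions,
    ShapeError,
    fit_interactions,
    fit_rowwise,
    forward,
    least_squares_oracle,
    objective_l1,
    objective_l2,
)

from conftest import make_expr, make_interaction


def _loop_norm(A, X, Y, norm):
    """Brute-force elementwise oracle for the residual norms."""
    total = 0.0
    n, K = Y.shape
    m = X.shape[0]
    for i in range(n):
        for k in range(K):
            yhat = sum(A[i, j] * X[j, k] for j in range(m))
            r = yhat - Y[i, k]
            total += abs(r) if norm == "l1" else r * r
    return total


class TestObjectives:
    def test_exact_solution_gives_zero(self, rng):
        A = rng.normal(size=(3, 4))
        X = rng.normal(size=(4, 6))
        Am, Xm = make_interaction(A), make_expr(X)
        Ym = forward(Am, Xm)
        assert objective_l1(Am, Xm, Ym) == 0.0
        assert objective_l2(Am, Xm, Ym) == 0.0

    def test_zero_matrix_reduces_to_norm_of_y(self):
        A = make_interaction(np.zeros((1, 2)))
        X = make_expr(np.ones((2, 2)))
        Y = make_expr([[1.0, -2.0]], genes=["t0"])
        assert objective_l1(A, X, Y) == pytest.approx(3.0)
        assert objective_l2(A, X, Y) == pytest.approx(5.0)

    def test_matches_loop_oracle_on_random_instances(self, rng):
        for _ in range(10):
            A = rng.normal(size=(3, 3))
            X = rng.normal(size=(3, 3))
            Y = rng.normal(size=(3, 3))
            Am, Xm = make_interaction(A), make_expr(X)
            Ym = make_expr(Y, genes=["t0", "t1", "t2"])
            assert objective_l1(Am, Xm, Ym) == pytest.approx(_loop_norm(A, X, Y, "l1"))
            assert objective_l2(Am, Xm, Ym) == pytest.approx(_loop_norm(A, X, Y, "l2"))

    def test_shape_mismatch_raises(self, rng):
        A = make_interaction(np.ones((2, 2)))
        X = make_expr(rng.normal(size=(2, 3)))
        Y = make_expr(rng.normal(size=(2, 2)))
        with pytest.raises(ShapeError):
            objective_l1(A, X, Y)


class TestFitOptions:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"method": "newton"},
            {"norm": "l3"},
            {"gtol": 0.0},
            {"max_iter": 0},
            {"init": "random"},
        ],
    )
    def test_invalid_options_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            FitOptions(**kwargs)


@pytest.mark.parametrize("fit", [fit_interactions, fit_rowwise], ids=["joint", "rowwise"])
class TestFit:
    def test_recovers_truth_and_matches_lsq_oracle(self, fit, rng):
        # overdetermined noiseless: unique solution under both norms
        X = make_expr(rng.lognormal(0, 1, size=(4, 10)), species="miRNA")
        A_true = make_interaction(-rng.uniform(0.2, 2.0, size=(4, 4)))
        Y = forward(A_true, X)
        oracle = least_squares_oracle(X, Y)
        for norm, tol in (("l2", 1e-6), ("l1", 1e-4)):
            res = fit(X, Y, FitOptions(norm=norm))
            assert np.abs(res.A_hat.values - A_true.values).max() <= tol
            assert np.abs(res.A_hat.values - oracle.values).max() <= tol
            assert res.converged

    def test_zero_target_converges_at_start(self, fit, rng):
        X = make_expr(rng.lognormal(0, 1, size=(3, 4)))
        Y = make_expr(np.zeros((2, 4)))
        res = fit(X, Y)
        np.testing.assert_array_equal(res.A_hat.values, 0.0)
        assert res.final_error == 0.0
        assert res.converged

    def test_final_error_consistent_with_objective(self, fit, rng):
        X = make_expr(rng.lognormal(0, 1, size=(3, 5)))
        Y = make_expr(rng.normal(size=(2, 5)))  # inconsistent (noisy) system
        res = fit(X, Y, FitOptions(norm="l2"))
        recomputed = objective_l2(res.A_hat, X, Y)
        assert res.final_error == pytest.approx(recomputed, rel=1e-12)
        assert res.per_row_error.sum() == pytest.approx(res.final_error, rel=1e-12)

    def test_deterministic(self, fit, rng):
        X = make_expr(rng.lognormal(0, 1, size=(4, 3)))
        Y = make_expr(rng.normal(size=(3, 3)))
        r1, r2 = fit(X, Y), fit(X, Y)
        np.testing.assert_array_equal(r1.A_hat.values, r2.A_hat.values)
        assert r1.final_error == r2.final_error

    def test_unaligned_panels_rejected(self, fit, rng):
        X = make_expr(rng.normal(size=(2, 3)), samples=["a", "b", "c"])
        Y = make_expr(rng.normal(size=(2, 3)), samples=["a", "b", "d"])
        with pytest.raises(ShapeError):
            fit(X, Y)


class TestRowwiseSpecifics:
    def test_monotone_descent_traces(self, rng):
        X = make_expr(rng.lognormal(0, 1, size=(5, 8)))
        Y = make_expr(rng.normal(size=(3, 8)))
        for norm in ("l1", "l2"):
            res = fit_rowwise(X, Y, FitOptions(norm=norm))
            for trace in res.traces:
                diffs = np.diff(trace)
                assert (diffs <= 1e-12).all(), "objective increased across iterations"

    def test_matches_joint_fit_on_consistent_system(self, rng):
        X = make_expr(rng.lognormal(0, 1, size=(3, 9)), species="miRNA")
        A_true = make_interaction(-rng.uniform(0.2, 2.0, size=(3, 3)))
        Y = forward(A_true, X)
        # tight gtol so both solvers run to gradient convergence
        opts = FitOptions(norm="l2", gtol=1e-22)
        rj = fit_interactions(X, Y, opts)
        rr = fit_rowwise(X, Y, opts)
        assert np.abs(rj.A_hat.values - rr.A_hat.values).max() <= 1e-8

    def test_single_row_equals_joint(self, rng):
        X = make_expr(rng.lognormal(0, 1, size=(3, 8)))
        Y = make_expr(rng.normal(size=(1, 8)))
        opts = FitOptions(norm="l2")
        np.testing.assert_allclose(
            fit_rowwise(X, Y, opts).A_hat.values,
            fit_interactions(X, Y, opts).A_hat.values,
            atol=1e-8,
        )

    def test_underdetermined_consistent_reconstructs_exactly(self, rng):
        # K < m: coefficients are ambiguous but the data are reproduced
        m, K = 10, 3
        X = make_expr(rng.lognormal(0, 1, size=(m, K)), species="miRNA")
        A_true = make_interaction(-rng.uniform(0.2, 2.0, size=(2, m)))
        Y = forward(A_true, X)
        res = fit_rowwise(X, Y)
        assert res.final_error <= 1e-6
        Y_rec = forward(res.A_hat, X)
        assert np.abs(Y_rec.values - Y.values).max() <= 1e-6
        # ...while the coefficients themselves are not identified
        assert np.abs(res.A_hat.values - A_true.values).max() > 1e-3
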