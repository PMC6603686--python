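"""ε-SVR contracts, cross-validation, GA search, and the OLS baseline."""

import numpy as np
import pytest

from pttbp.models import (
    DEFAULT_SVR_PARAMS,
    GAConfig,
    SVRParams,
    cross_validate,
    decode_chromosome,
    fit_mlr,
    fit_svr,
    ga_optimize,
    predict_svr,
)

from _oracle import qp_svr_predict


@pytest.fixture
def tiny_problem(rng):
    X = rng.normal(size=(8, 2))
    y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
    return X, y


class TestFitSvr:
    def test_constant_target_inside_tube_has_no_support_vectors(self):
        X = np.arange(10, dtype=float)[:, None]
        y = np.full(10, 4.2)
        model = fit_svr(X, y, SVRParams(c=1.0, gamma=0.5, epsilon=0.1))
        assert model.dual_coef.size == 0
        assert np.allclose(predict_svr(model, X), 4.2, atol=1e-6)

    def test_wide_tube_covers_data_with_zero_duals(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12) * 0.1
        eps = float(np.max(np.abs(y - np.median(y)))) + 0.05
        model = fit_svr(X, y, SVRParams(c=5.0, gamma=0.3, epsilon=eps))
        assert model.dual_coef.size == 0
        assert np.all(np.abs(y - predict_svr(model, X)) <= eps + 1e-9)

    def test_dual_box_constraint(self, tiny_problem):
        X, y = tiny_problem
        params = SVRParams(c=2.0, gamma=0.7, epsilon=0.05)
        model = fit_svr(X, y, params)
        assert np.all(np.abs(model.dual_coef) <= params.c + 1e-9)

    def test_training_points_of_well_fit_model_within_epsilon(self, tiny_problem):
        X, y = tiny_problem
        params = SVRParams(c=100.0, gamma=0.5, epsilon=0.05)
        model = fit_svr(X, y, params, tol=1e-8)
        assert np.all(np.abs(y - predict_svr(model, X)) <= params.epsilon + 1e-4)

    def test_nonfinite_rejected(self):
        X = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError, match="finite"):
            fit_svr(X, np.zeros(2), DEFAULT_SVR_PARAMS)

    def test_matches_qp_oracle(self, rng):
        for _ in range(3):
            n, p = int(rng.integers(5, 11)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            params = SVRParams(
                c=float(rng.uniform(0.5, 10)),
                gamma=float(rng.uniform(0.1, 2)),
                epsilon=float(rng.uniform(0.01, 0.2)),
            )
            Xq = rng.normal(size=(4, p))
            model = fit_svr(X, y, params, tol=1e-8)
            oracle = qp_svr_predict(X, y, params.c, params.gamma, params.epsilon, Xq)
            assert np.max(np.abs(predict_svr(model, Xq) - oracle)) < 1e-4


class TestPredictSvr:
    def test_far_query_with_large_gamma_tends_to_bias(self, tiny_problem):
        X, y = tiny_problem
        model = fit_svr(X, y, SVRParams(c=10.0, gamma=500.0, epsilon=0.01))
        far = np.full((1, 2), 50.0)
        assert predict_svr(model, far)[0] == pytest.approx(model.intercept, abs=1e-9)

    def test_dimension_mismatch_rejected(self, tiny_problem):
        X, y = tiny_problem
        model = fit_svr(X, y, DEFAULT_SVR_PARAMS)
        with pytest.raises(ValueError, match="features"):
            predict_svr(model, np.zeros((3, 5)))

    def test_serialization_round_trip(self, tiny_problem):
        from pttbp.models import SVRModel

        X, y = tiny_problem
        model = fit_svr(X, y, SVRParams(c=3.0, gamma=0.4, epsilon=0.05))
        back = SVRModel.from_dict(model.to_dict())
        Xq = np.random.default_rng(0).normal(size=(5, 2))
        assert np.allclose(predict_svr(back, Xq), predict_svr(model, Xq))


class TestCrossValidate:
    def test_reproducible_target_gives_zero_mse(self):
        # constant y with epsilon covering it: every fold predicts exactly
        X = np.arange(20, dtype=float)[:, None]
        y = np.full(20, 3.0)
        assert cross_validate(X, y, SVRParams(1.0, 0.5, 0.1)) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_same_seed_same_folds(self, tiny_problem, rng):
        X = rng.normal(size=(30, 2))
        y = X[:, 0] ** 2
        p = SVRParams(5.0, 0.5, 0.05)
        assert cross_validate(X, y, p, seed=4) == cross_validate(X, y, p, seed=4)

    def test_leave_one_out_matches_direct_enumeration(self, rng):
        X = rng.normal(size=(10, 1))
        y = np.cos(X[:, 0])
        p = SVRParams(2.0, 0.8, 0.01)
        loo = cross_validate(X, y, p, k=10, seed=1, tol=1e-6)
        order = np.random.default_rng(1).permutation(10)
        direct = []
        for i in order:
            mask = np.ones(10, dtype=bool)
            mask[i] = False
            m = fit_svr(X[mask], y[mask], p, tol=1e-6)
            direct.append((y[i] - predict_svr(m, X[[i]])[0]) ** 2)
        assert loo == pytest.approx(np.mean(direct))

    def test_k_less_than_two_rejected(self, tiny_problem):
        X, y = tiny_problem
        with pytest.raises(ValueError):
            cross_validate(X, y, DEFAULT_SVR_PARAMS, k=1)


class TestGaOptimize:
    def test_chromosome_endpoint_decoding(self):
        cfg = GAConfig()
        nb = 3 * cfg.bits_per_param
        zeros = decode_chromosome(np.zeros(nb, dtype=bool), cfg)
        ones = decode_chromosome(np.ones(nb, dtype=bool), cfg)
        assert zeros.c == pytest.approx(1e-6)  # clamped positivity floor
        assert zeros.gamma == pytest.approx(1e-6)
        assert zeros.epsilon == pytest.approx(0.01)
        assert ones.c == pytest.approx(100.0)
        assert ones.gamma == pytest.approx(1000.0)
        assert ones.epsilon == pytest.approx(1.0)

    def test_best_curve_nonincreasing_and_result_beats_defaults(self, rng):
        X = rng.uniform(size=(120, 3))
        y = 50 + 20 * X[:, 0] + 10 * np.sin(3 * X[:, 1]) + rng.normal(0, 0.5, 120)
        cfg = GAConfig(pop_size=12, max_gen=10, seed=2, fit_tol=1e-3)
        res = ga_optimize(X, y, cfg)
        assert all(a >= b for a, b in zip(res.best_mse_per_gen,
                                          res.best_mse_per_gen[1:]))
        default_mse = cross_validate(X, y, DEFAULT_SVR_PARAMS, seed=cfg.seed,
                                     tol=1e-3)
        assert res.best_mse <= default_mse
        assert len(res.best_mse_per_gen) == cfg.max_gen

    def test_no_variation_operators_never_worsens_best(self, rng):
        X = rng.uniform(size=(60, 2))
        y = X[:, 0] * 10
        cfg = GAConfig(pop_size=6, max_gen=6, p_crossover=0.0, p_mutation=0.0,
                       seed=5, fit_tol=1e-3)
        res = ga_optimize(X, y, cfg)
        assert res.best_mse_per_gen[-1] <= res.best_mse_per_gen[0]

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            GAConfig(c_range=(5.0, 5.0)).validate()


class TestFitMlr:
    def test_exact_linear_data_recovered(self, rng):
        X = rng.normal(size=(40, 3))
        beta = np.array([2.0, -1.5, 0.25])
        y = 7.0 + X @ beta
        model = fit_mlr(X, y)
        assert model.intercept == pytest.approx(7.0)
        assert np.allclose(model.coef, beta)
        assert np.allclose(model.predict(X), y)

    def test_small_noise_consistency(self, rng):
        X = rng.normal(size=(2000, 1))
        y = 3.0 + 2.0 * X[:, 0] + rng.normal(0, 1e-4, 2000)
        model = fit_mlr(X, y)
        assert model.intercept == pytest.approx(3.0, abs=1e-4)
        assert model.coef[0] == pytest.approx(2.0, abs=1e-4)

    def test_single_feature_matches_closed_form_slope(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        model = fit_mlr(x[:, None], y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coef[0] == pytest.approx(slope)

    def test_collinear_design_names_offender(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 1.0 - x])
        with pytest.raises(ValueError, match="S2"):
            fit_mlr(X, rng.normal(size=30), feature_names=["S1", "S2"])
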