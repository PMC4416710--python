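"""Solver correctness: closed forms, proximal operator, KKT, references."""

import numpy as np
import pytest

from sglmri.model import (
    PenaltyConfig,
    SparseGroupLogit,
    classify,
    neg_mean_loglik,
    objective,
    predict_proba,
    prox,
)

from _oracles import (
    kkt_violation,
    numeric_prox,
    numeric_sgl_fit,
    prox_objective,
    sgl_penalized_objective,
)


def random_problem(rng, n=20, d=6, n_groups=2):
    X = rng.normal(size=(n, d))
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    membership = np.sort(rng.integers(0, n_groups, size=d))
    membership[:n_groups] = np.arange(n_groups)  # every group nonempty
    return X, y, np.sort(membership)


class TestClosedForms:
    def test_zero_weights_give_half_probability(self, rng):
        X = rng.normal(size=(5, 4))
        assert np.allclose(predict_proba(X, np.zeros(4)), 0.5)

    def test_log_odds_identity(self):
        # x'w = ln 3  ->  P(+1) = 0.75
        x = np.array([np.log(3.0)])
        w = np.array([1.0])
        assert np.isclose(predict_proba(x, w)[0], 0.75)

    def test_probability_matches_formula(self, rng):
        x = rng.normal(size=7)
        w = rng.normal(size=7)
        brute = 1.0 / (1.0 + np.exp(-float(x @ w)))
        assert np.isclose(predict_proba(x, w)[0], brute, rtol=1e-12)
        assert np.isclose(
            predict_proba(x, w)[0] + 1.0 / (1.0 + np.exp(float(x @ w))), 1.0
        )

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            predict_proba(np.ones(3), np.ones(4))

    def test_f_at_zero_is_ln2(self, rng):
        X, y, _ = random_problem(rng)
        assert neg_mean_loglik(np.zeros(6), X, y) == pytest.approx(np.log(2), abs=1e-15)

    def test_f_decreases_along_separating_direction(self, rng):
        X = np.vstack([np.ones((5, 1)), -np.ones((5, 1))])
        y = np.array([1.0] * 5 + [-1.0] * 5)
        vals = [neg_mean_loglik(np.array([t]), X, y) for t in (1, 10, 100)]
        assert vals[0] > vals[1] > vals[2] >= 0

    def test_f_matches_term_by_term_sum(self, rng):
        X, y, _ = random_problem(rng, n=9)
        w = rng.normal(size=6)
        brute = -np.mean(
            [np.log(1.0 / (1.0 + np.exp(-yi * (xi @ w)))) for xi, yi in zip(X, y)]
        )
        assert np.isclose(neg_mean_loglik(w, X, y), brute, rtol=1e-12)

    def test_objective_l1_arithmetic(self, rng):
        X, y, _ = random_problem(rng, d=2, n_groups=1)
        w = np.array([1.0, -2.0])
        pen = PenaltyConfig(1.0, 0.0)
        assert objective(w, X, y, pen) == pytest.approx(neg_mean_loglik(w, X, y) + 3.0)

    def test_objective_group_norm(self, rng):
        X, y, _ = random_problem(rng, d=2, n_groups=1)
        w = np.array([3.0, 4.0])
        pen = PenaltyConfig(0.0, 1.0)
        m = np.zeros(2, dtype=int)
        assert objective(w, X, y, pen, m) == pytest.approx(
            neg_mean_loglik(w, X, y) + 5.0
        )

    def test_objective_matches_independent_recomputation(self, rng):
        X, y, m = random_problem(rng, d=8, n_groups=3)
        w = rng.normal(size=8)
        pen = PenaltyConfig(0.3, 0.7)
        assert objective(w, X, y, pen, m) == pytest.approx(
            sgl_penalized_objective(w, X, y, 0.3, 0.7, m), rel=1e-12
        )


class TestClassify:
    def test_sign_rule_with_tie_to_healthy(self):
        w = np.array([1.0])
        assert classify(np.array([[0.1]]), w)[0] == 1
        assert classify(np.array([[0.0]]), w)[0] == -1
        assert classify(np.array([[-0.1]]), w)[0] == -1

    def test_batch_equals_sign_oracle(self, rng):
        X = rng.normal(size=(50, 4))
        w = rng.normal(size=4)
        expected = np.where(X @ w > 0, 1, -1)
        assert np.array_equal(classify(X, w), expected)


class TestProx:
    def test_no_penalty_is_identity(self, rng):
        v = rng.normal(size=6)
        assert np.array_equal(prox(v, 0.5, PenaltyConfig(0, 0)), v)

    def test_group_shrink_closed_form(self):
        v = np.array([3.0, 4.0])
        z = prox(v, 1.0, PenaltyConfig(0.0, 1.0), np.zeros(2, int))
        assert np.allclose(z, [2.4, 3.2])

    def test_soft_threshold_closed_form(self):
        v = np.array([2.0, -0.5, 0.2])
        z = prox(v, 1.0, PenaltyConfig(0.4, 0.0))
        assert np.allclose(z, [1.6, -0.1, 0.0])

    def test_matches_numerical_minimization(self, rng):
        """Closed-form prox agrees with generic minimization of its objective."""
        for _ in range(10):
            v = rng.normal(size=10) * 2
            step = rng.uniform(0.1, 2.0)
            ls, lg = rng.uniform(0, 1, size=2)
            m = np.sort(rng.integers(0, 3, size=10))
            z = prox(v, step, PenaltyConfig(ls, lg), m)
            q = numeric_prox(v, step, ls, lg, m)
            assert abs(
                prox_objective(z, v, step, ls, lg, m)
                - prox_objective(q, v, step, ls, lg, m)
            ) <= 1e-6


class TestFit:
    def test_l1_zero_threshold_exact(self, rng):
        X, y, _ = random_problem(rng)
        g0 = -(X.T @ (y * 0.5)) / len(y)
        res = SparseGroupLogit(y, X).fit(PenaltyConfig(np.max(np.abs(g0)), 0.0))
        assert np.all(res.params == 0.0)
        assert res.converged

    def test_group_zero_threshold_exact(self, rng):
        X, y, m = random_problem(rng)
        g0 = -(X.T @ (y * 0.5)) / len(y)
        lam = max(np.linalg.norm(g0[m == g]) for g in np.unique(m))
        res = SparseGroupLogit(y, X, groups=m).fit(PenaltyConfig(0.0, lam))
        assert np.all(res.params == 0.0)

    def test_matches_generic_solver_and_kkt(self, rng):
        """Objective within 1e-6 relative of an independent minimizer; KKT holds."""
        for trial in range(5):
            X, y, m = random_problem(rng, n=20, d=6, n_groups=2)
            ls = rng.uniform(0.01, 0.1)
            lg = rng.uniform(0.01, 0.2)
            res = SparseGroupLogit(y, X, groups=m).fit(
                PenaltyConfig(ls, lg), max_iter=20000, tol=1e-14
            )
            _, oracle_val = numeric_sgl_fit(X, y, ls, lg, m, seed=trial)
            ours = sgl_penalized_objective(res.params, X, y, ls, lg, m)
            assert ours <= oracle_val + 1e-6 * abs(oracle_val)
            assert abs(ours - oracle_val) <= 1e-6 * abs(oracle_val)
            assert kkt_violation(res.params, X, y, ls, lg, m) < 1e-5

    def test_matches_sklearn_l1_reference(self, rng):
        """Pure-L1 special case agrees with liblinear's L1 logistic fit."""
        from sklearn.linear_model import LogisticRegression

        X, y, _ = random_problem(rng, n=30, d=8)
        ls = 0.05
        res = SparseGroupLogit(y, X).fit(PenaltyConfig(ls, 0.0), max_iter=10000, tol=1e-14)
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / (30 * ls), solver="liblinear",
            fit_intercept=False, tol=1e-10, max_iter=10000,
        )
        clf.fit(X, y)
        pen = PenaltyConfig(ls, 0.0)
        ours = objective(res.params, X, y, pen)
        theirs = objective(clf.coef_.ravel(), X, y, pen)
        assert abs(ours - theirs) <= 1e-6 * abs(theirs)

    def test_singleton_groups_reduce_to_l1(self, rng):
        X, y, _ = random_problem(rng)
        lam = 0.07
        l1 = SparseGroupLogit(y, X).fit(PenaltyConfig(lam, 0.0), tol=1e-12)
        singleton = SparseGroupLogit(y, X, groups=np.arange(6)).fit(
            PenaltyConfig(0.0, lam), tol=1e-12
        )
        assert np.allclose(l1.params, singleton.params, atol=1e-6)

    def test_trace_monotone_and_bounded_by_ln2(self, rng):
        X, y, m = random_problem(rng, n=30, d=10, n_groups=3)
        res = SparseGroupLogit(y, X, groups=m).fit(PenaltyConfig(0.02, 0.05))
        assert res.objective_value <= np.log(2) + 1e-12
        assert np.all(np.diff(res.solver_trace) <= 1e-12)
        assert res.objective_value == pytest.approx(
            objective(res.params, X, y, res.penalty, m), abs=1e-10
        )

    def test_objective_convexity_spot_check(self, rng):
        X, y, m = random_problem(rng, d=8, n_groups=3)
        pen = PenaltyConfig(0.3, 0.4)
        for _ in range(20):
            w1, w2 = rng.normal(size=(2, 8))
            a = rng.random()
            lhs = objective(a * w1 + (1 - a) * w2, X, y, pen, m)
            rhs = a * objective(w1, X, y, pen, m) + (1 - a) * objective(w2, X, y, pen, m)
            assert lhs <= rhs + 1e-12

    def test_nonfinite_data_rejected(self, rng):
        X, y, _ = random_problem(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            SparseGroupLogit(y, X)

    def test_unpenalized_highdim_warns(self, rng):
        X = rng.normal(size=(4, 10))
        y = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.warns(UserWarning):
            SparseGroupLogit(y, X).fit(PenaltyConfig(0.0, 0.0), max_iter=10)


class TestPath:
    def test_large_lambda_endpoint_empty_support(self, rng):
        X, y, m = random_problem(rng, n=30, d=10, n_groups=3)
        g0 = -(X.T @ (y * 0.5)) / 30
        big = 2 * np.max(np.abs(g0))
        model = SparseGroupLogit(y, X, groups=m)
        path = model.fit_path([PenaltyConfig(big, 0.0), PenaltyConfig(0.01, 0.0)])
        assert path[0].support.size == 0
        assert path[1].support.size > 0

    def test_warm_start_matches_cold_start(self, rng):
        X, y, m = random_problem(rng, n=30, d=10, n_groups=3)
        lams = np.geomspace(0.3, 0.01, 8)
        model = SparseGroupLogit(y, X, groups=m)
        warm = model.fit_path([PenaltyConfig(l, 0.0) for l in lams], tol=1e-12)
        for res in warm:
            cold = model.fit(res.penalty, tol=1e-12)
            assert abs(res.objective_value - cold.objective_value) <= 1e-6

    def test_support_shrinks_along_increasing_lambda(self, small_dataset):
        _, fm, groups, _ = small_dataset
        model = SparseGroupLogit(fm.labels, fm.values, groups=groups)
        lams = np.geomspace(0.01, 0.3, 10)
        path = model.fit_path([PenaltyConfig(l, 0.0) for l in lams], tol=1e-7)
        sizes = {r.penalty.lambda_s: r.support.size for r in path}
        assert sizes[lams[-1]] <= sizes[lams[0]]
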