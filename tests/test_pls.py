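"""NIPALS PLS1, LOO cross-validation, VIP and Spearman utilities."""

import numpy as np
import pytest
from scipy import stats

from psychoscreen.pls import (
    fit_pls,
    loo_cv,
    select_components,
    spearman,
    vip,
)


def ols_predictions(x, y):
    """Normal-equation least squares with intercept (reference oracle)."""
    design = np.column_stack([np.ones(len(y)), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return design @ beta


def naive_loo(x, y, n_components, scale):
    """Explicit n-refit leave-one-out loop (reference oracle)."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        model = fit_pls(x[mask], y[mask], n_components, scale=scale)
        preds[i] = model.predict(x[i])[0]
    return preds


class TestFitPLS:
    def test_single_direction_signal(self, rng):
        x = np.zeros((30, 4))
        x[:, 0] = rng.normal(size=30)
        y = 3.0 * x[:, 0]
        model = fit_pls(x, y, 1, scale=False)
        resid = y - model.predict(x)
        assert 1 - resid.var() / y.var() >= 0.999

    def test_full_rank_equals_ols(self, rng):
        x = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = fit_pls(x, y, 5, scale=False)
        np.testing.assert_allclose(model.predict(x), ols_predictions(x, y), atol=1e-6)

    def test_scores_orthogonal(self, rng):
        x = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        model = fit_pls(x, y, 5, scale=True)
        gram = model.scores.T @ model.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_coefficient_path_equals_deflation_predictions(self, rng):
        """Predictions from (W, P, q) via b must equal X·b + intercept."""
        x = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        model = fit_pls(x, y, 3, scale=True)
        xc = (x - model.x_mean) / model.scaling
        manual = model.y_mean + model.scores @ model.y_loadings
        np.testing.assert_allclose(model.predict(x), manual, atol=1e-10)
        assert np.allclose(xc @ (model.coefficients * model.scaling) + model.y_mean,
                           model.predict(x), atol=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        x = rng.normal(size=(30, 7))
        y = x[:, 0] - 0.5 * x[:, 3] + rng.normal(0, 0.3, 30)
        for a in (1, 3, 5):
            mine = fit_pls(x, y, a, scale=True)
            ref = PLSRegression(n_components=a, scale=True).fit(x, y)
            np.testing.assert_allclose(mine.predict(x),
                                       ref.predict(x).ravel(), atol=1e-8)

    def test_row_permutation_invariance(self, rng):
        x = rng.normal(size=(18, 5))
        y = rng.normal(size=18)
        model = fit_pls(x, y, 3, scale=True)
        perm = rng.permutation(18)
        permuted = fit_pls(x[perm], y[perm], 3, scale=True)
        np.testing.assert_allclose(permuted.coefficients, model.coefficients,
                                   atol=1e-10)
        np.testing.assert_allclose(permuted.scores, model.scores[perm], atol=1e-10)

    def test_zero_variance_column_named(self, rng):
        x = rng.normal(size=(12, 3))
        x[:, 1] = 5.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_pls(x, rng.normal(size=12), 2, scale=True)


class TestVIP:
    def test_single_predictor_vip_is_one(self, rng):
        x = rng.normal(size=(15, 1))
        y = 2 * x[:, 0] + rng.normal(0, 0.1, 15)
        model = fit_pls(x, y, 1, scale=True)
        assert vip(model)[0] == pytest.approx(1.0, abs=1e-12)

    def test_squares_average_to_one(self, rng):
        for _ in range(10):
            n, p = rng.integers(12, 30), rng.integers(2, 9)
            x = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            model = fit_pls(x, y, min(3, p), scale=True)
            scores = vip(model)
            assert np.sum(scores**2) == pytest.approx(p, abs=1e-8)

    def test_signal_column_dominates(self, rng):
        hits = 0
        for _ in range(20):
            x = rng.normal(size=(200, 10))
            y = x[:, 0] + rng.normal(0, 0.5, 200)
            model = fit_pls(x, y, 2, scale=True)
            scores = vip(model)
            hits += int(np.argmax(scores) == 0 and scores[0] > 1)
        assert hits >= 19

    def test_invariant_to_positive_scaling_of_y(self, rng):
        x = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        v1 = vip(fit_pls(x, y, 3, scale=True))
        v2 = vip(fit_pls(x, 7.5 * y, 3, scale=True))
        np.testing.assert_allclose(v1, v2, atol=1e-10)


class TestLooCV:
    def test_equals_naive_refit_loop(self, rng):
        for _ in range(5):
            x = rng.normal(size=(15, 4))
            y = rng.normal(size=15)
            ev = loo_cv(x, y, 3, scale=True)
            np.testing.assert_allclose(ev.loo_predictions,
                                       naive_loo(x, y, 3, True), atol=1e-10)

    def test_noiseless_linear_data_high_q2(self, rng):
        x = rng.normal(size=(30, 3))
        y = x @ np.array([1.0, -2.0, 0.5])
        ev = loo_cv(x, y, 3, scale=False)
        assert ev.q2 >= 0.999

    def test_evaluation_identities(self, rng):
        x = rng.normal(size=(20, 4))
        y = x[:, 0] + rng.normal(0, 0.5, 20)
        ev = loo_cv(x, y, 2, scale=True)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert ev.q2 == pytest.approx(1 - ev.press / ss_tot, abs=1e-12)
        assert ev.rmsecv == pytest.approx(np.sqrt(ev.press / len(y)), abs=1e-12)
        assert 0 <= ev.spearman_p <= 1 and ev.q2 <= 1

    def test_permuted_response_mean_q2_nonpositive(self, rng):
        q2s = []
        for _ in range(50):
            x = rng.normal(size=(30, 5))
            y = rng.permutation(x[:, 0] + rng.normal(0, 0.2, 30))
            q2s.append(loo_cv(x, y, 2, scale=True).q2)
        assert np.mean(q2s) <= 0

    def test_q2_never_beats_training_r2(self, rng):
        for _ in range(10):
            x = rng.normal(size=(25, 6))
            y = x[:, 0] + rng.normal(0, 1.0, 25)
            a = int(rng.integers(1, 5))
            model = fit_pls(x, y, a, scale=True)
            r2 = 1 - np.sum((y - model.predict(x)) ** 2) / np.sum((y - y.mean()) ** 2)
            assert loo_cv(x, y, a, scale=True).q2 <= r2 + 1e-8


class TestSelectComponents:
    def test_single_factor_data(self, rng):
        t = rng.normal(size=40)
        x = np.outer(t, rng.normal(size=6)) + rng.normal(0, 0.05, (40, 6))
        y = t + rng.normal(0, 0.05, 40)
        a_star, _ = select_components(x, y, 4, scale=True)
        assert a_star == 1

    def test_ties_break_toward_smaller(self):
        # engineered directly on the documented rule
        q2 = np.array([0.3, 0.5, 0.5])
        best = int(np.argmax(q2 > q2.max() - 1e-12)) + 1
        assert best == 2

    def test_two_latent_components_recovered(self, rng):
        """Two orthogonal latent blocks with very different X-variance and a
        response weighted toward the minor block: one greedy component
        cannot span the predictive subspace, so LOO-Q² selects A = 2."""
        hits = 0
        for _ in range(40):
            t1 = rng.normal(0, 5, 100)
            t2 = rng.normal(0, 1, 100)
            p1 = np.r_[np.ones(5), np.zeros(5)]
            p2 = np.r_[np.zeros(5), np.ones(5)]
            x = np.outer(t1, p1) + np.outer(t2, p2) + rng.normal(0, 0.2, (100, 10))
            y = 0.1 * t1 + t2 + rng.normal(0, 0.1, 100)
            a_star, _ = select_components(x, y, 5, scale=True)
            hits += int(a_star == 2)
        assert hits >= 32  # >= 80% of seeds


class TestSpearman:
    def test_monotone_transform_gives_unit_r(self, rng):
        x = rng.normal(size=12)
        r, p = spearman(x, np.exp(x))
        assert r == 1.0 and p < 1e-6

    def test_reversed_ranks_give_minus_one(self):
        x = np.arange(8.0)
        r, _ = spearman(x, x[::-1])
        assert r == -1.0

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        r, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_permutation_close_to_t_approx(self, rng):
        for _ in range(30):
            x, y = rng.normal(size=6), rng.normal(size=6)
            _, p_t = spearman(x, y, p_method="t_approx")
            _, p_e = spearman(x, y, p_method="exact_perm")
            assert abs(p_t - p_e) < 0.05

    def test_exact_permutation_matches_scipy_exhaustive(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        _, p_e = spearman(x, y, p_method="exact_perm")
        res = stats.permutation_test(
            (x, y), lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings", n_resamples=np.inf, alternative="two-sided")
        assert p_e == pytest.approx(res.pvalue, abs=1e-12)

    def test_constant_vector_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(6), np.arange(6.0))

    def test_exact_refused_for_large_n(self, rng):
        with pytest.raises(ValueError, match="n <= 8"):
            spearman(rng.normal(size=9), rng.normal(size=9), p_method="exact_perm")
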