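import itertools

import numpy as np
import pytest

from conftest import AnalyticModel, linear_model
from icufair import interpret as itp
from icufair.models import make_model

ZEROS = itp.BaselineSpec("zeros")


def quadratic_model(d=1):
    return AnalyticModel(
        fn=lambda X: X[:, 0] ** 2,
        grad=lambda X: np.column_stack([2 * X[:, 0]] + [np.zeros(len(X))] * (d - 1)),
    )


class TestSaliency:
    def test_linear_model_returns_coefficients(self):
        attr = itp.saliency(linear_model([2.0, 3.0]), np.array([[5.0, -1.0]]))
        assert attr.importance.tolist() == [[2.0, 3.0]]

    def test_constant_model_all_zero(self):
        m = AnalyticModel(fn=lambda X: np.full(len(X), 0.3), grad=lambda X: np.zeros_like(X))
        assert not itp.saliency(m, np.ones((4, 3))).signed.any()

    def test_matches_finite_differences_on_mlp(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 5))
        y = (X[:, 0] > 0).astype(int)
        m = make_model("mlp").fit(X, y, seed=0)
        g = itp.saliency(m, X[:2]).signed
        eps = 1e-5
        for j in range(5):
            xp, xm = X[0].copy(), X[0].copy()
            xp[j] += eps
            xm[j] -= eps
            fd = (m.predict_proba(xp[None])[0] - m.predict_proba(xm[None])[0]) / (2 * eps)
            assert g[0, j] == pytest.approx(fd, rel=1e-3, abs=1e-8)

    def test_requires_gradients(self):
        class NoGrad(AnalyticModel):
            gradient_available = False

        m = NoGrad(fn=lambda X: X[:, 0], grad=None)
        with pytest.raises(itp.CapabilityError):
            itp.saliency(m, np.ones((1, 2)))


class TestIntegratedGradients:
    def test_linear_closed_form_and_completeness(self):
        m = linear_model([2.0, 3.0])
        attr = itp.integrated_gradients(m, np.array([[1.0, 2.0]]), ZEROS)
        assert np.allclose(attr.signed, [[2.0, 6.0]])
        assert attr.signed.sum() == pytest.approx(8.0)

    def test_input_equal_baseline_gives_zero(self):
        m = linear_model([2.0, 3.0])
        attr = itp.integrated_gradients(m, np.zeros((1, 2)), ZEROS)
        assert not attr.signed.any()

    def test_quadratic_integral(self):
        attr = itp.integrated_gradients(
            quadratic_model(), np.array([[1.0]]), ZEROS, itp.InterpreterConfig(ig_steps=2000)
        )
        assert attr.signed[0, 0] == pytest.approx(1.0, abs=1e-3)


class TestGradientShap:
    def test_linear_analytic_expectation(self):
        w = np.array([1.5, -2.0, 0.5])
        m = linear_model(w)
        x = np.array([[2.0, 1.0, -1.0]])
        bl = itp.BaselineSpec("distribution_sampler", seed=0,
                              sampler=lambda rng, k, d: rng.normal(0, 0.1, size=(k, d)))
        attr = itp.gradient_shap(m, x, bl, itp.InterpreterConfig(noise_std=0.0, noise_draws=200))
        assert np.allclose(attr.signed, w * x, rtol=0.05, atol=0.02)

    def test_zero_noise_zero_baseline_matches_ig_for_linear(self):
        m = linear_model([2.0, 3.0])
        x = np.array([[1.0, 2.0]])
        gs = itp.gradient_shap(m, x, ZEROS, itp.InterpreterConfig(noise_std=0.0, noise_draws=10))
        ig = itp.integrated_gradients(m, x, ZEROS)
        assert np.allclose(gs.signed, ig.signed)

    def test_seeded_determinism(self):
        m = quadratic_model(2)
        x = np.array([[1.0, 2.0]])
        cfg = itp.InterpreterConfig(seed=5)
        a = itp.gradient_shap(m, x, itp.BaselineSpec(seed=1), cfg).signed
        b = itp.gradient_shap(m, x, itp.BaselineSpec(seed=1), cfg).signed
        assert np.array_equal(a, b)


class TestSaliencyNoiseTunnel:
    def test_linear_equals_saliency_any_std(self):
        m = linear_model([1.0, -4.0])
        x = np.array([[0.5, 0.5]])
        nt = itp.saliency_noise_tunnel(m, x, config=itp.InterpreterConfig(noise_std=2.0))
        assert np.allclose(nt.signed, itp.saliency(m, x).signed)

    def test_zero_std_equals_saliency(self):
        m = quadratic_model(2)
        x = np.array([[1.5, 0.0]])
        nt = itp.saliency_noise_tunnel(m, x, config=itp.InterpreterConfig(noise_std=0.0))
        assert np.allclose(nt.signed, itp.saliency(m, x).signed)

    def test_variance_shrinks_with_draws(self):
        m = quadratic_model(1)
        x = np.array([[1.0]])

        def spread(draws):
            vals = [
                itp.saliency_noise_tunnel(
                    m, x, config=itp.InterpreterConfig(noise_std=0.5, noise_draws=draws, seed=s)
                ).signed[0, 0]
                for s in range(20)
            ]
            return np.var(vals)

        assert spread(1000) < spread(10) / 10


class TestShapleySampling:
    def test_product_model_splits_evenly(self):
        m = AnalyticModel(fn=lambda X: X[:, 0] * X[:, 1], grad=None)
        attr = itp.shapley_sampling(
            m, np.array([[1.0, 1.0]]), ZEROS, itp.InterpreterConfig(shapley_draws=400, seed=0)
        )
        assert np.allclose(attr.signed, [[0.5, 0.5]], atol=0.06)

    def test_additive_model_exact_for_any_permutations(self):
        w = np.array([1.0, -2.0, 3.0])
        m = linear_model(w, b=0.5)
        x = np.array([[2.0, 1.0, -1.0]])
        attr = itp.shapley_sampling(m, x, ZEROS, itp.InterpreterConfig(shapley_draws=3, seed=9))
        assert np.allclose(attr.signed, w * x)

    def test_matches_brute_force_shapley(self):
        d = 6
        rng = np.random.default_rng(3)
        Q = rng.normal(size=(d, d)) * 0.3
        w = rng.normal(size=d)
        m = AnalyticModel(fn=lambda X: np.einsum("ni,ij,nj->n", X, Q, X) + X @ w, grad=None)
        x = rng.normal(size=d)

        def value(subset):
            z = np.zeros((1, d))
            z[0, list(subset)] = x[list(subset)]
            return m.predict_proba(z)[0]

        exact = np.zeros(d)
        perms = list(itertools.permutations(range(d)))
        for perm in perms:
            acc: list[int] = []
            prev = value(acc)
            for j in perm:
                acc.append(j)
                cur = value(acc)
                exact[j] += cur - prev
                prev = cur
        exact /= len(perms)
        # efficiency: exact Shapley values sum to M(x) - M(0)
        assert exact.sum() == pytest.approx(m.predict_proba(x[None])[0] - m.predict_proba(np.zeros((1, d)))[0])

        est = itp.shapley_sampling(
            m, x[None, :], ZEROS, itp.InterpreterConfig(shapley_draws=2000, seed=1)
        ).signed[0]
        assert np.max(np.abs(est - exact)) < 0.05


class TestFeaturePermutation:
    def test_identical_rows_score_zero(self):
        m = linear_model([1.0, 2.0])
        X = np.ones((5, 2))
        attr = itp.feature_permutation(m, X)
        assert not attr.signed.any()

    def test_ignored_feature_scores_zero(self):
        m = AnalyticModel(fn=lambda X: X[:, 0], grad=None)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        attr = itp.feature_permutation(m, X)
        assert np.allclose(attr.signed[:, 1:], 0.0)

    def test_two_point_batch_expected_half(self):
        # batch x1 in {0,1}: the shuffle is identity (score 0) or a swap
        # (score 1) with equal probability, so the mean over seeds -> 0.5
        m = AnalyticModel(fn=lambda X: X[:, 0], grad=None)
        X = np.array([[0.0], [1.0]])
        scores = [
            itp.feature_permutation(m, X, config=itp.InterpreterConfig(seed=s)).signed[0, 0]
            for s in range(200)
        ]
        assert set(np.unique(scores)) <= {0.0, 1.0}
        assert abs(np.mean(scores) - 0.5) < 0.11  # 3 binomial SE


class TestFeatureAblation:
    def test_linear_closed_form(self):
        attr = itp.feature_ablation(linear_model([2.0, 3.0]), np.array([[1.0, 1.0]]), ZEROS)
        assert np.allclose(attr.signed, [[2.0, 3.0]])

    def test_feature_at_baseline_scores_zero(self):
        attr = itp.feature_ablation(linear_model([2.0, 3.0]), np.array([[0.0, 1.0]]), ZEROS)
        assert attr.signed[0, 0] == 0.0

    def test_equals_occlusion_with_unit_window(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 6))
        m = AnalyticModel(fn=lambda Z: np.tanh(Z @ np.arange(6.0)), grad=None)
        abl = itp.feature_ablation(m, X, ZEROS)
        occ = itp.occlusion(m, X, ZEROS, itp.InterpreterConfig(input_shape=(2, 3)))
        assert np.allclose(abl.signed, occ.signed)


class TestOcclusion:
    def test_two_step_window_averages_covering_deltas(self):
        # additive model over a T=3, F=1 grid with a 2x1 time window:
        # cell 0 <- delta(window 0); cell 1 <- mean of both; cell 2 <- delta(window 1)
        w = np.array([1.0, 2.0, 4.0])
        m = linear_model(w)
        x = np.array([[1.0, 1.0, 1.0]])
        occ = itp.occlusion(
            m, x, ZEROS, itp.InterpreterConfig(input_shape=(3, 1), occlusion_window=(2, 1))
        )
        d0, d1 = w[0] + w[1], w[1] + w[2]
        assert np.allclose(occ.signed, [[d0, (d0 + d1) / 2, d1]])

    def test_full_window_gives_total_output_change(self):
        m = linear_model([1.0, 2.0, 3.0, 4.0])
        x = np.array([[1.0, 1.0, 1.0, 1.0]])
        occ = itp.occlusion(
            m, x, ZEROS, itp.InterpreterConfig(input_shape=(2, 2), occlusion_window=(2, 2))
        )
        assert np.allclose(occ.signed, 10.0)


class TestArchDetect:
    def test_linear_gives_squared_coefficients(self):
        m = linear_model([2.0, 3.0], b=1.0)
        attr = itp.arch_detect(m, np.array([[1.0, 1.0]]))
        assert np.allclose(attr.signed, [[4.0, 9.0]])

    def test_zero_input_convention(self):
        m = linear_model([2.0, 3.0])
        attr = itp.arch_detect(m, np.array([[0.0, 1.0]]))
        assert attr.signed[0, 0] == 0.0

    def test_quadratic_difference_quotient(self):
        attr = itp.arch_detect(quadratic_model(), np.array([[2.0]]))
        assert attr.signed[0, 0] == pytest.approx(4.0)


class TestGlassboxAndRandom:
    def test_glassbox_broadcasts_model_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = (X[:, 1] > 0).astype(int)
        m = make_model("attention_glassbox").fit(X, y, seed=0)
        attr = itp.glassbox(m, X[:7])
        assert attr.signed.shape == (7, 4)
        assert np.allclose(attr.signed, attr.signed[0])
        assert np.allclose(attr.signed.sum(axis=1), 1.0)

    def test_glassbox_requires_capability(self):
        with pytest.raises(itp.CapabilityError):
            itp.glassbox(linear_model([1.0]), np.ones((1, 1)))

    def test_random_ranking_is_seeded_permutation(self):
        a = itp.random_ranking(8, seed=3, n_samples=2)
        b = itp.random_ranking(8, seed=3, n_samples=2)
        assert np.array_equal(a.signed, b.signed)
        for row in a.signed:
            assert sorted(row) == list(range(1, 9))

    def test_different_seeds_differ(self):
        a = itp.random_ranking(10, seed=1).signed
        b = itp.random_ranking(10, seed=2).signed
        assert not np.array_equal(a, b)


class TestAggregateGlobalRank:
    def test_two_sample_average(self):
        # feature a ranks (1, 3); feature b ranks (2, 1) -> order (b, a)
        imp = np.array([[3.0, 2.0, 1.0], [1.0, 3.0, 2.0]])
        order = itp.aggregate_global_rank(itp.Attribution(imp, "t"))
        assert order[0] == 1 and order[1] == 0

    def test_single_sample_matches_its_own_order(self):
        imp = np.array([[0.1, 0.9, 0.5]])
        order = itp.aggregate_global_rank(itp.Attribution(imp, "t"))
        assert order.tolist() == [1, 2, 0]

    def test_identical_samples_stable(self):
        imp = np.tile(np.array([[0.2, 0.8, 0.5]]), (20, 1))
        order = itp.aggregate_global_rank(itp.Attribution(imp, "t"))
        assert order.tolist() == [1, 2, 0]


class TestCrossMethodInvariants:
    def test_linear_concordance_of_rankings(self):
        w = np.array([0.5, -1.5, 1.0, -0.2])
        m = linear_model(w)
        x = np.full((1, 4), 2.0)  # all inputs equal and positive
        rank_by_w = np.argsort(-np.abs(w), kind="stable")
        for fn in (itp.saliency, itp.feature_ablation, itp.arch_detect, itp.integrated_gradients):
            attr = fn(m, x, ZEROS)
            got = np.argsort(-attr.importance[0], kind="stable")
            assert np.array_equal(got, rank_by_w), fn.__name__

    def test_null_feature_scores_zero(self):
        m = AnalyticModel(
            fn=lambda X: np.tanh(X[:, 0]), grad=lambda X: np.column_stack([1 - np.tanh(X[:, 0]) ** 2, np.zeros(len(X))])
        )
        x = np.array([[0.7, 5.0]])
        for fn in (itp.saliency, itp.integrated_gradients, itp.feature_ablation, itp.arch_detect):
            assert fn(m, x, ZEROS).importance[0, 1] == pytest.approx(0.0, abs=1e-12), fn.__name__
        sh = itp.shapley_sampling(m, x, ZEROS, itp.InterpreterConfig(shapley_draws=25))
        assert sh.importance[0, 1] == pytest.approx(0.0, abs=1e-8)
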