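"""Mixture fitting, membership weights, and the T0-T3 standardized scores."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.mixture import GaussianMixture

from tdaseq import gmm


def make_fit(weights, means, variances):
    return gmm.GMMFit(
        len(weights), np.asarray(weights, float), np.asarray(means, float),
        np.asarray(variances, float), 0.0, True, 0,
    )


FIT_2C = make_fit([0.5, 0.5], [0.0, 4.0], [1.0, 1.0])


class TestLogTransform:
    def test_pseudo_count_exact_powers_of_two(self):
        vec = gmm.log_transform([1, 3, 7], pseudo_count=1)
        np.testing.assert_allclose(vec.values, [1.0, 2.0, 3.0])
        assert vec.n_dropped == 0

    def test_drop_zeros_without_pseudo_count(self):
        vec = gmm.log_transform([0, 4], pseudo_count=0)
        np.testing.assert_allclose(vec.values, [2.0])
        assert vec.n_dropped == 1

    def test_all_zero_with_zero_pseudo_count_errors(self):
        with pytest.raises(ValueError, match="zero"):
            gmm.log_transform([0, 0], pseudo_count=0)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            gmm.log_transform([-1.0, 2.0])


class TestFitGMM:
    def test_single_component_is_sample_moments(self, rng):
        x = rng.normal(2.0, 3.0, 500)
        fit = gmm.fit_gmm(x, n_components=1, seed=0)
        assert fit.means[0] == pytest.approx(np.mean(x))
        assert fit.variances[0] == pytest.approx(np.var(x))
        assert fit.converged

    def test_constant_vector_raises_variance_collapse(self):
        with pytest.raises(ValueError, match="[Vv]ariance"):
            gmm.fit_gmm(np.full(100, 3.0), n_components=2, seed=0)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            gmm.fit_gmm(rng.normal(size=15), n_components=2, seed=0)

    def test_em_log_likelihood_monotone(self, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1.5, 500)])
        fit = gmm.fit_gmm(x, n_components=2, seed=3)
        diffs = np.diff(fit.ll_trajectory)
        assert np.all(diffs >= -1e-8)
        assert fit.converged

    def test_components_sorted_by_mean(self, rng):
        x = np.concatenate([rng.normal(8, 1, 400), rng.normal(-2, 1, 400)])
        fit = gmm.fit_gmm(x, n_components=2, seed=0)
        assert fit.means[0] < fit.means[1]

    def test_parameter_recovery_and_sklearn_cross_check(self):
        rng = np.random.default_rng(11)
        n = 5000
        comp = rng.random(n) < 0.4
        x = rng.normal(np.where(comp, 3.12, 8.87), np.where(comp, 2.61, 2.11))
        fit = gmm.fit_gmm(x, n_components=2, seed=0)
        assert fit.means == pytest.approx([3.12, 8.87], abs=0.3)
        # independent EM route: sklearn must not find a materially better optimum
        sk = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
        sk_ll = sk.score(x[:, None]) * n
        assert fit.log_likelihood >= sk_ll - 1e-3 * abs(sk_ll)

    def test_parameter_recovery_improves_with_sample_size(self):
        errs = []
        for n in (500, 20000):
            rng = np.random.default_rng(5)
            comp = rng.random(n) < 0.4
            x = rng.normal(np.where(comp, 3.12, 8.87),
                           np.where(comp, 2.61, 2.11))
            fit = gmm.fit_gmm(x, n_components=2, seed=0)
            errs.append(
                np.max(np.abs(fit.means - [3.12, 8.87]))
                + np.max(np.abs(fit.sds - [2.61, 2.11]))
            )
        assert errs[1] < errs[0]


class TestMixtureDensity:
    def test_standard_normal_mode(self):
        fit = make_fit([1.0], [0.0], [1.0])
        assert gmm.mixture_pdf(fit, 0.0) == pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_symmetric_mixture_cdf_at_midpoint(self):
        fit = make_fit([0.5, 0.5], [-2.0, 2.0], [1.5, 1.5])
        assert gmm.mixture_cdf(fit, 0.0) == pytest.approx(0.5)

    def test_two_term_hand_evaluation(self):
        fit = make_fit([0.3, 0.7], [0.0, 4.0], [1.0, 1.0])
        expected_pdf = (
            0.3 * math.exp(-2.0) / math.sqrt(2 * math.pi)
            + 0.7 * math.exp(-2.0) / math.sqrt(2 * math.pi)
        )
        assert gmm.mixture_pdf(fit, 2.0) == pytest.approx(expected_pdf, rel=1e-12)
        expected_cdf = 0.3 * stats.norm.cdf(2.0) + 0.7 * stats.norm.cdf(-2.0)
        assert gmm.mixture_cdf(fit, 2.0) == pytest.approx(expected_cdf, rel=1e-12)

    def test_cdf_monotone_with_correct_tails(self):
        fit = make_fit([0.4, 0.6], [3.12, 8.87], [2.61**2, 2.11**2])
        grid = np.linspace(-30, 40, 300)
        cdf = gmm.mixture_cdf(fit, grid)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[0] == pytest.approx(0.0, abs=1e-9)
        assert cdf[-1] == pytest.approx(1.0, abs=1e-9)


class TestAssignments:
    def test_single_component_weight_is_one(self):
        fit = make_fit([1.0], [0.0], [1.0])
        w = gmm.membership_weights(fit, [1.7])
        np.testing.assert_allclose(w.weights, [[1.0]])

    def test_symmetric_midpoint_is_half_half(self):
        w = gmm.membership_weights(FIT_2C, [2.0])
        np.testing.assert_allclose(w.weights, [[0.5, 0.5]], atol=1e-12)

    def test_density_ratio_hand_value(self):
        # at x=0: omega_1 = phi(0) / (phi(0) + phi(4)) = 1 / (1 + e^-8)
        w = gmm.membership_weights(FIT_2C, [0.0])
        assert w.weights[0, 0] == pytest.approx(1 / (1 + math.exp(-8)), rel=1e-12)

    def test_extreme_tail_never_nan(self):
        fit = make_fit([0.5, 0.5], [0.0, 4.0], [0.01, 0.01])
        w = gmm.membership_weights(fit, [-500.0, 500.0])
        assert np.all(np.isfinite(w.weights))
        np.testing.assert_allclose(w.weights.sum(axis=1), 1.0)

    @pytest.mark.parametrize(
        "soft,expected",
        [([0.9, 0.1], [1, 0]), ([0.5, 0.5], [1, 0]), ([0.2, 0.8], [0, 1])],
    )
    def test_hard_assignment_with_lower_mean_tie_break(self, soft, expected):
        hard = gmm.hard_assignment(
            gmm.AssignmentWeights("soft", np.array([soft]))
        )
        np.testing.assert_allclose(hard.weights, [expected])

    @settings(deadline=None, max_examples=30)
    @given(st.floats(-20, 20))
    def test_weights_always_sum_to_one(self, x):
        for mode_fn in (lambda w: w, gmm.hard_assignment):
            w = mode_fn(gmm.membership_weights(FIT_2C, [x]))
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-9)


class TestScores:
    def test_single_component_collapse_to_zscore(self, rng):
        fit = make_fit([1.0], [2.0], [4.0])
        x = rng.normal(2, 2, 50)
        soft = gmm.membership_weights(fit, x)
        z = (x - 2.0) / 2.0
        for fn in (gmm.score_T1, gmm.score_T2, gmm.score_T3):
            np.testing.assert_allclose(fn(fit, x, soft), z, rtol=1e-12)
        np.testing.assert_allclose(gmm.score_T0_observed(fit, x), z, rtol=1e-12)

    def test_symmetric_midpoint_scores_vanish(self):
        soft = gmm.membership_weights(FIT_2C, [2.0])
        for fn in (gmm.score_T1, gmm.score_T2, gmm.score_T3):
            assert fn(FIT_2C, [2.0], soft)[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluation_chain_at_x_equals_one(self):
        x = np.array([1.0])
        soft = gmm.membership_weights(FIT_2C, x)
        w1 = 1 / (1 + math.exp(0.5 * (1.0 - 9.0)))  # phi ratio at x=1
        mu_bar = w1 * 0.0 + (1 - w1) * 4.0
        expected_t1 = (w1 + (1 - w1)) * (1.0 - mu_bar)
        expected_t2 = (w1 * 1.0 + (1 - w1) * 1.0) ** -0.5 * (1.0 - mu_bar)
        total = w1 * (1.0 + mu_bar**2) + (1 - w1) * (1.0 + (4.0 - mu_bar) ** 2)
        expected_t3 = total**-0.5 * (1.0 - mu_bar)
        assert gmm.score_T1(FIT_2C, x, soft)[0] == pytest.approx(expected_t1)
        assert gmm.score_T2(FIT_2C, x, soft)[0] == pytest.approx(expected_t2)
        assert gmm.score_T3(FIT_2C, x, soft)[0] == pytest.approx(expected_t3)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-10, 14))
    def test_t3_never_exceeds_t2_in_magnitude(self, x):
        fit = make_fit([0.4, 0.6], [0.0, 5.0], [1.0, 2.0])
        soft = gmm.membership_weights(fit, [x])
        t2 = gmm.score_T2(fit, [x], soft)[0]
        t3 = gmm.score_T3(fit, [x], soft)[0]
        assert abs(t3) <= abs(t2) + 1e-12

    def test_t0_latent_agrees_with_observed_when_assignment_correct(self):
        fit = make_fit([0.5, 0.5], [0.0, 10.0], [1.0, 1.0])
        x = np.array([0.5, 9.5])
        true = np.array([0, 1])
        np.testing.assert_allclose(
            gmm.score_T0_latent(fit, x, true),
            gmm.score_T0_observed(fit, x),
        )

    def test_t0_latent_misassignment_branches(self):
        fit = make_fit([0.5, 0.5], [0.0, 4.0], [1.0, 4.0])
        tau = math.sqrt(1.0 / 4.0)
        delta = (0.0 - 4.0) / 2.0
        # x=3.9 is hard-assigned high (s~1 < s1) but truly from the low comp
        x = np.array([3.9])
        z = (3.9 - 0.0) / 1.0
        expected = tau * z + tau * delta
        assert gmm.score_T0_latent(fit, x, [0])[0] == pytest.approx(expected)
        # x=0.1 assigned low (s~1 > s1) but truly from the high comp
        z2 = (0.1 - 4.0) / 2.0
        expected2 = z2 / tau - delta
        assert gmm.score_T0_latent(fit, [0.1], [1])[0] == pytest.approx(expected2)

    def test_t0_latent_requires_two_components(self):
        fit = make_fit([1.0], [0.0], [1.0])
        with pytest.raises(ValueError, match="two-component"):
            gmm.score_T0_latent(fit, [0.0], [0])

    def test_observed_t0_zero_at_component_mean(self):
        assert gmm.score_T0_observed(FIT_2C, [0.0])[0] == pytest.approx(0.0)
        assert gmm.score_T0_observed(FIT_2C, [4.0])[0] == pytest.approx(0.0)


class TestGoodnessOfFit:
    def test_single_observation_at_median_gives_half(self):
        fit = make_fit([1.0], [0.0], [1.0])
        rep = gmm.ks_goodness_of_fit(np.array([0.0]), fit)
        assert rep.ks_statistic == pytest.approx(0.5)

    def test_sample_from_fitted_mixture_rarely_rejected(self):
        fit = make_fit([0.4, 0.6], [3.12, 8.87], [2.61**2, 2.11**2])
        rejections = 0
        for rep_seed in range(100):
            rng = np.random.default_rng(rep_seed)
            comp = rng.random(1000) < 0.4
            x = rng.normal(np.where(comp, 3.12, 8.87),
                           np.where(comp, 2.61, 2.11))
            rejections += gmm.ks_goodness_of_fit(x, fit, alpha=0.01).reject
        assert rejections <= 5

    def test_sample_outside_support_rejected(self, rng):
        fit = make_fit([1.0], [0.0], [1.0])
        rep = gmm.ks_goodness_of_fit(rng.uniform(100, 200, 50), fit)
        assert rep.reject
        assert rep.ks_statistic > 0.99

    def test_reject_flag_tracks_alpha(self, rng):
        fit = make_fit([1.0], [0.0], [1.0])
        rep = gmm.ks_goodness_of_fit(rng.normal(0, 1, 200), fit, alpha=0.01)
        assert rep.reject == (rep.p_value < rep.alpha)


class TestQQ:
    def test_exact_quantiles_lie_on_diagonal(self):
        n = 40
        scores = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        theo, emp = gmm.qq_points(scores)
        np.testing.assert_allclose(theo, emp, atol=1e-12)
        assert gmm.qq_slope(scores) == pytest.approx(1.0, abs=1e-9)

    def test_two_point_plotting_positions(self):
        theo, emp = gmm.qq_points([1.0, -1.0])
        np.testing.assert_allclose(
            theo, [stats.norm.ppf(0.25), stats.norm.ppf(0.75)]
        )
        np.testing.assert_allclose(emp, [-1.0, 1.0])


class TestScoreMatrix:
    def test_small_cohort_matrix_shapes_and_gof(self, small_cohort, small_scores):
        scores, fits, gof = small_scores
        assert scores.shape == (
            small_cohort.fpkm.shape[1], small_cohort.fpkm.shape[0],
        )
        assert set(gof.columns) >= {"subject_id", "D", "p_value", "reject"}
        assert len(fits) == small_cohort.fpkm.shape[1]
        assert np.all(np.isfinite(scores.to_numpy()))

    def test_zero_pseudo_count_with_zeros_rejected(self, small_cohort):
        fpkm = small_cohort.fpkm.iloc[:50, :5].copy()
        fpkm.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="pseudo_count"):
            gmm.compute_score_matrix(fpkm, pseudo_count=0.0)
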