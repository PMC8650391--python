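import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import ndtr

from augresp.latent_model import (
    FitOptions,
    LatentModelError,
    LatentParameters,
    fit_latent_model,
    gof_residuals,
    loglikelihood,
    pack_parameters,
    response_probability,
    response_probability_gradient,
    unpack_parameters,
)
from augresp.effect_estimation import _fd_prob_gradient
from augresp.synthetic_data import generate
from augresp.trial_data import EndpointSpec, TrialDataset

from conftest import random_correlation


def _single_subject(y, ybin, baselines, arm=0):
    nc = len(y)
    return TrialDataset(
        subject_id=np.array(["s"]),
        arm=np.array([arm]),
        y_cont=np.array([y], dtype=float),
        y_bin=None if ybin is None else np.array([ybin]),
        baselines=np.array([baselines], dtype=float),
    )


def _quadrature_loglik(params, data, spec):
    """Independent oracle: per subject, numerically integrate the joint
    normal density of (y_cont, latent) over the binary outcome's latent
    half-line."""
    D = np.diag(np.append(params.sigma, 1.0))
    Sig = D @ params.R @ D
    total = 0.0
    for i in range(data.n_subjects):
        mu_c = params.mean(data.arm[[i]], data.baselines[[i]])[0]
        mu = np.append(mu_c, params.alpha_b + params.beta_b * data.arm[i])

        def dens(z):
            pt = np.append(data.y_cont[i], z)
            return stats.multivariate_normal.pdf(pt, mean=mu, cov=Sig)

        if data.y_bin[i] == 1:
            val, _ = integrate.quad(dens, 0, np.inf, epsabs=1e-13, epsrel=1e-11)
        else:
            val, _ = integrate.quad(dens, -np.inf, 0, epsabs=1e-13, epsrel=1e-11)
        total += math.log(val)
    return total


class TestLoglikelihood:
    def test_independent_standard_mode_value(self):
        # two continuous at their means with unit scales and no correlation,
        # binary observed 1 with latent mean 0:
        # 2 log(1/sqrt(2 pi)) + log(1/2) = -2.5310243
        params = LatentParameters(
            alpha=np.zeros(2), beta=np.zeros(2), gamma=np.zeros(2),
            sigma=np.ones(2), alpha_b=0.0, beta_b=0.0, R=np.eye(3),
        )
        spec = EndpointSpec(2, True, (0.0, 0.0))
        data = _single_subject([0.0, 0.0], 1, [0.0, 0.0])
        ll = loglikelihood(params, data, spec)
        assert ll == pytest.approx(-2.5310243, abs=1e-6)

    def test_translation_invariance(self, simple_params, simple_spec):
        data = generate(simple_params, 25, [(0.0, 1.0)], seed=3)
        ll = loglikelihood(simple_params, data, simple_spec)
        c = 17.3
        shifted = TrialDataset(
            subject_id=data.subject_id,
            arm=data.arm,
            y_cont=data.y_cont + c,
            y_bin=data.y_bin,
            baselines=data.baselines,
        )
        moved = LatentParameters(
            alpha=simple_params.alpha + c,
            beta=simple_params.beta,
            gamma=simple_params.gamma,
            sigma=simple_params.sigma,
            alpha_b=simple_params.alpha_b,
            beta_b=simple_params.beta_b,
            R=simple_params.R,
        )
        assert loglikelihood(moved, shifted, simple_spec) == pytest.approx(
            ll, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        R = random_correlation(rng)
        params = LatentParameters(
            alpha=rng.normal(0, 1, 2),
            beta=rng.normal(0, 0.5, 2),
            gamma=rng.normal(0, 0.4, 2),
            sigma=rng.uniform(0.5, 2.0, 2),
            alpha_b=rng.normal(0, 0.5),
            beta_b=rng.normal(0, 0.5),
            R=R,
        )
        spec = EndpointSpec(2, True, (0.0, 0.0))
        data = generate(params, 5, [(0.0, 1.0), (0.0, 1.0)], seed=100 + seed)
        ll = loglikelihood(params, data, spec)
        assert ll == pytest.approx(_quadrature_loglik(params, data, spec),
                                   abs=1e-6)

    def test_non_positive_definite_R_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            LatentParameters(
                alpha=np.zeros(2), beta=np.zeros(2), gamma=np.zeros(2),
                sigma=np.ones(2), alpha_b=0.0, beta_b=0.0, R=bad,
            )


class TestPacking:
    def test_roundtrip(self, preset):
        params, spec, _ = preset
        back = unpack_parameters(pack_parameters(params), spec)
        np.testing.assert_allclose(back.R, params.R, atol=1e-12)
        np.testing.assert_allclose(back.sigma, params.sigma, atol=1e-12)
        np.testing.assert_allclose(back.alpha, params.alpha, atol=1e-12)
        assert back.alpha_b == pytest.approx(params.alpha_b, abs=1e-12)

    def test_parameter_count(self, preset, simple_params):
        params, _, _ = preset
        assert params.n_parameters == 4 * 2 + 2 + 3 == 13
        assert simple_params.n_parameters == 4 + 2 + 1 == 7


class TestFit:
    def test_recovers_truth_within_3se(self, preset):
        params, spec, baseline_law = preset
        data = generate(params, 2000, baseline_law, seed=99)
        fit = fit_latent_model(data, spec)
        se = np.sqrt(np.diag(fit.vcov))
        err = np.abs(fit.theta - pack_parameters(params))
        assert np.all(err < 3 * se), (err / se).round(2)

    def test_loglik_not_below_truth_on_tiny_data(self, preset):
        params, spec, baseline_law = preset
        data = generate(params, 30, baseline_law, seed=5)
        fit = fit_latent_model(data, spec)
        assert fit.loglik >= loglikelihood(params, data, spec) - 1e-8

    def test_null_treatment_coefficient_coverage(self, simple_spec):
        null = LatentParameters(
            alpha=np.array([0.5]), beta=np.array([0.0]),
            gamma=np.array([0.4]), sigma=np.array([1.3]),
            alpha_b=-0.2, beta_b=0.0,
            R=np.array([[1.0, -0.45], [-0.45, 1.0]]),
        )
        # theta layout: [a1, b1, g1, log s1, ab, bb, w]
        beta_idx = [1, 5]
        cover = np.zeros(2)
        n_rep = 100
        for r in range(n_rep):
            data = generate(null, 60, [(0.0, 1.0)], seed=700 + r)
            fit = fit_latent_model(data, simple_spec)
            se = np.sqrt(np.diag(fit.vcov))
            for k, idx in enumerate(beta_idx):
                lo = fit.theta[idx] - 1.959964 * se[idx]
                hi = fit.theta[idx] + 1.959964 * se[idx]
                cover[k] += lo <= 0.0 <= hi
        assert np.all(cover / n_rep >= 0.90), cover / n_rep

    def test_guard_rail_small_arm(self, simple_params, simple_spec):
        data = generate(simple_params, 8, [(0.0, 1.0)], seed=1)
        with pytest.raises(LatentModelError, match="at least 10"):
            fit_latent_model(data, simple_spec)

    def test_separation_rejected(self, simple_params, simple_spec):
        data = generate(simple_params, 20, [(0.0, 1.0)], seed=2)
        sep = TrialDataset(
            subject_id=data.subject_id,
            arm=data.arm,
            y_cont=data.y_cont,
            y_bin=np.ones(data.n_subjects, dtype=int),
            baselines=data.baselines,
        )
        with pytest.raises(LatentModelError, match="separated"):
            fit_latent_model(sep, simple_spec)

    def test_correlations_strictly_inside_unit_interval(self, preset_fit):
        R = preset_fit.mle.R
        off = R[~np.eye(R.shape[0], dtype=bool)]
        assert np.all(np.abs(off) < 1.0)

    def test_collapses_to_ols_without_binary(self):
        # one continuous component, no binary: MLE must equal least squares
        spec = EndpointSpec(1, False, (0.0,))
        rng = np.random.default_rng(8)
        n = 400
        arm = np.repeat([0, 1], n // 2)
        base = rng.normal(0, 1, n)
        y = 1.0 - 0.6 * arm + 0.5 * base + rng.normal(0, 1.2, n)
        data = TrialDataset(
            subject_id=np.arange(n).astype(object),
            arm=arm,
            y_cont=y[:, None],
            y_bin=None,
            baselines=base[:, None],
        )
        fit = fit_latent_model(data, spec)
        X = np.column_stack([np.ones(n), arm, base])
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.mle.alpha[0] == pytest.approx(ols[0], abs=1e-6)
        assert fit.mle.beta[0] == pytest.approx(ols[1], abs=1e-6)
        assert fit.mle.gamma[0] == pytest.approx(ols[2], abs=1e-6)
        resid = y - X @ ols
        assert fit.mle.sigma[0] == pytest.approx(
            math.sqrt(np.mean(resid**2)), abs=1e-5
        )
        # and the response probability is the averaged normal CDF
        p = response_probability(fit.mle, 0, data.baselines, spec)
        mu = fit.mle.alpha[0] + fit.mle.gamma[0] * base
        assert p == pytest.approx(
            float(np.mean(ndtr((0.0 - mu) / fit.mle.sigma[0]))), abs=1e-9
        )


class TestResponseProbability:
    def test_independence_factorizes(self):
        params = LatentParameters(
            alpha=np.array([0.2, -0.1]), beta=np.array([0.3, 0.1]),
            gamma=np.array([0.5, -0.2]), sigma=np.array([1.0, 2.0]),
            alpha_b=0.3, beta_b=-0.2, R=np.eye(3),
        )
        spec = EndpointSpec(2, True, (0.5, -0.2))
        basel = np.array([[0.7, 1.1]])
        p = response_probability(params, 1, basel, spec)
        mu = params.mean(np.array([1]), basel)[0]
        marg = (
            ndtr((0.5 - mu[0]) / 1.0)
            * ndtr((-0.2 - mu[1]) / 2.0)
            * ndtr(params.alpha_b + params.beta_b)
        )
        assert p == pytest.approx(marg, abs=1e-10)

    def test_infinite_thresholds_give_one(self):
        params = LatentParameters(
            alpha=np.array([0.0, 0.0]), beta=np.array([0.0, 0.0]),
            gamma=np.array([0.0, 0.0]), sigma=np.array([1.0, 1.0]),
            alpha_b=None, beta_b=None,
            R=np.array([[1.0, 0.3], [0.3, 1.0]]),
        )
        spec = EndpointSpec(2, False, (np.inf, np.inf))
        p = response_probability(params, 0, np.zeros((1, 2)), spec)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_oracle_on_preset(self, preset):
        params, spec, baseline_law = preset
        n = 400_000
        data = generate(params, n, baseline_law, seed=123)
        mask = data.arm == 0
        from augresp.trial_data import classify_responders

        # classify by the model's own region (strict thresholds; the
        # boundary has measure zero for continuous draws)
        resp = classify_responders(data, spec)[mask]
        mc = resp.mean()
        p = response_probability(params, 0, data.baselines[mask], spec)
        se = math.sqrt(mc * (1 - mc) / mask.sum())
        assert abs(p - mc) < 3 * se

    def test_monotone_in_threshold_and_binary_effect(self, preset):
        params, spec, _ = preset
        basel = np.array([[10.0, 1.5], [8.0, 1.0]])
        base_p = response_probability(params, 1, basel, spec)
        wider = EndpointSpec(
            spec.n_cont, spec.has_binary,
            (spec.thresholds[0] + 1.0, spec.thresholds[1]),
        )
        assert response_probability(params, 1, basel, wider) >= base_p
        boosted = LatentParameters(
            alpha=params.alpha, beta=params.beta, gamma=params.gamma,
            sigma=params.sigma, alpha_b=params.alpha_b,
            beta_b=params.beta_b + 0.5, R=params.R,
        )
        assert response_probability(boosted, 1, basel, spec) >= base_p

    def test_bounded(self, preset_fit, preset_data, preset):
        _, spec, _ = preset
        for arm in (0, 1):
            p = response_probability(
                preset_fit.mle, arm, preset_data.baselines, spec
            )
            assert 0.0 <= p <= 1.0

    def test_analytic_gradient_matches_central_differences(
        self, preset_fit, preset_data, preset
    ):
        _, spec, _ = preset
        for arm in (0, 1):
            _, g_ana = response_probability_gradient(
                preset_fit.mle, arm, preset_data.baselines, spec
            )
            g_fd = _fd_prob_gradient(preset_fit, preset_data, spec, arm,
                                     "empirical")
            np.testing.assert_allclose(g_ana, g_fd, atol=5e-7)


class TestGof:
    def test_zero_residual_at_fitted_mean(self, preset_fit, preset):
        params, spec, _ = preset
        mu = preset_fit.mle.mean(np.array([0]), np.array([[10.0, 1.5]]))[0]
        data = TrialDataset(
            subject_id=np.array(["a", "b"]),
            arm=np.array([0, 1]),
            y_cont=np.vstack([mu, mu + 1.0]),
            y_bin=np.array([1, 0]),
            baselines=np.array([[10.0, 1.5], [10.0, 1.5]]),
        )
        gof = gof_residuals(preset_fit, data, spec)
        assert gof.residuals_sq[0] == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_gives_sum_of_squares(self):
        params = LatentParameters(
            alpha=np.zeros(2), beta=np.zeros(2), gamma=np.zeros(2),
            sigma=np.ones(2), alpha_b=0.0, beta_b=0.0, R=np.eye(3),
        )
        spec = EndpointSpec(2, True, (0.0, 0.0))
        from augresp.latent_model import FitResult

        fit = FitResult(
            mle=params, loglik=0.0, vcov=np.eye(13), converged=True,
            n_iter=0, gradient_norm=0.0,
            theta=pack_parameters(params), spec=spec,
        )
        y = np.array([[0.6, -1.2], [1.0, 0.5]])
        data = TrialDataset(
            subject_id=np.array(["a", "b"]),
            arm=np.array([0, 1]),
            y_cont=y,
            y_bin=np.array([1, 0]),
            baselines=np.zeros((2, 2)),
        )
        gof = gof_residuals(fit, data, spec)
        np.testing.assert_allclose(gof.residuals_sq, (y**2).sum(axis=1),
                                   atol=1e-12)

    def test_ks_calibrated_under_correct_model(self, preset):
        # data simulated from the fitted model: the KS distance should stay
        # below the asymptotic 1% critical value nearly always
        params, spec, baseline_law = preset
        n_rep, ok = 40, 0
        for r in range(n_rep):
            data = generate(params, 500, baseline_law, seed=4000 + r)
            fit = fit_latent_model(data, spec)
            gof = gof_residuals(fit, data, spec)
            crit = 1.62762 / math.sqrt(data.n_subjects)
            ok += gof.ks_distance < crit
        assert ok >= math.ceil(0.95 * n_rep), ok

    def test_quantiles_are_plotting_positions(self, preset_fit, preset_data,
                                              preset):
        from scipy.stats import chi2

        _, spec, _ = preset
        gof = gof_residuals(preset_fit, preset_data, spec)
        n = preset_data.n_subjects
        expected = chi2.ppf((np.arange(1, n + 1) - 0.5) / n, spec.n_cont)
        np.testing.assert_allclose(gof.theoretical_quantiles, expected)
        assert np.all(np.diff(gof.sorted_residuals_sq) >= 0)
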