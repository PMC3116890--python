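import numpy as np
import pytest
from scipy import stats

from levmodel.inversion import (GaussianDensity, VLSettings,
                                integrate_coupling_step2,
                                invert_electrical_step1,
                                invert_hemodynamic_step3, multistep_invert,
                                variational_laplace)
from levmodel.priors import ParamSpec, coupling_specs, step3_specs
from levmodel.simulator import generate_synthetic_dataset


class TestVariationalLaplaceOracle:
    """Conjugate linear-Gaussian problems where the exact evidence and
    posterior are available in closed form."""

    def test_scalar_mean_model(self):
        # y_i = theta + e, prior N(0,1), sigma = 1, four observations of 1.0
        y = np.ones(4)
        prior = GaussianDensity(np.zeros(1), np.eye(1))
        settings = VLSettings(noise_mode="fixed", sigma0=1.0)
        res = variational_laplace(lambda m: np.full(4, m[0]), y, prior,
                                  settings)
        assert res.posterior.mean[0] == pytest.approx(0.8, abs=1e-9)
        assert res.posterior.cov[0, 0] == pytest.approx(0.2, abs=1e-9)
        # closed-form log evidence: N(y; 0, I + J J^T)
        cov_y = np.eye(4) + np.ones((4, 4))
        log_ev = stats.multivariate_normal.logpdf(y, mean=np.zeros(4),
                                                  cov=cov_y)
        assert res.free_energy == pytest.approx(log_ev, rel=1e-6)

    def test_general_linear_model(self, rng):
        # y = X b + e with known sigma; F equals the marginal likelihood
        n, p = 30, 3
        x_mat = rng.normal(size=(n, p))
        prior = GaussianDensity(np.zeros(p), np.diag([1.0, 2.0, 0.5]))
        sigma = 0.7
        y = rng.normal(size=n)
        settings = VLSettings(noise_mode="fixed", sigma0=sigma)
        res = variational_laplace(lambda m: x_mat @ m, y, prior, settings)
        post_prec = x_mat.T @ x_mat / sigma**2 + np.linalg.inv(prior.cov)
        post_cov = np.linalg.inv(post_prec)
        post_mean = post_cov @ (x_mat.T @ y) / sigma**2
        np.testing.assert_allclose(res.posterior.mean, post_mean, atol=1e-8)
        np.testing.assert_allclose(res.posterior.cov, post_cov, atol=1e-8)
        cov_y = sigma**2 * np.eye(n) + x_mat @ prior.cov @ x_mat.T
        log_ev = stats.multivariate_normal.logpdf(y, mean=np.zeros(n),
                                                  cov=cov_y)
        assert res.free_energy == pytest.approx(log_ev, rel=1e-6)

    def test_huge_noise_returns_prior(self):
        y = np.ones(4) * 10
        prior = GaussianDensity(np.zeros(1), np.eye(1))
        settings = VLSettings(noise_mode="fixed", sigma0=1e6)
        res = variational_laplace(lambda m: np.full(4, m[0]), y, prior,
                                  settings)
        assert abs(res.posterior.mean[0]) < 1e-6
        assert res.posterior.cov[0, 0] == pytest.approx(1.0, rel=1e-6)

    def test_tight_prior_pins_posterior(self):
        y = np.ones(4)
        prior = GaussianDensity(np.zeros(1), np.eye(1) * 1e-12)
        settings = VLSettings(noise_mode="fixed", sigma0=1.0)
        res = variational_laplace(lambda m: np.full(4, m[0]), y, prior,
                                  settings)
        assert abs(res.posterior.mean[0]) < 1e-6


class TestVariationalLaplaceBehaviour:
    def test_f_trajectory_monotone_nonlinear(self, rng):
        # mildly nonlinear forward model: exponential decay
        t = np.linspace(0, 3, 40)
        truth = np.array([0.4, -0.3])

        def predict(m):
            return (1 + m[0]) * np.exp(-(1 + m[1]) * t)

        y = predict(truth) + rng.normal(0, 0.05, size=t.size)
        prior = GaussianDensity(np.zeros(2), np.eye(2))
        res = variational_laplace(predict, y, prior, VLSettings())
        f = np.array(res.f_trajectory)
        assert np.all(np.diff(f) >= -1e-9)
        np.testing.assert_allclose(res.posterior.mean, truth, atol=0.15)
        assert res.residual_sd == pytest.approx(0.05, rel=0.4)

    def test_nonfinite_data_rejected(self):
        prior = GaussianDensity(np.zeros(1), np.eye(1))
        with pytest.raises(ValueError):
            variational_laplace(lambda m: m, np.array([np.nan]), prior)

    def test_estimated_noise_matches_truth(self, rng):
        t = np.linspace(0, 1, 200)
        y = 2.0 * t + rng.normal(0, 0.3, size=t.size)
        prior = GaussianDensity(np.zeros(1), np.eye(1) * 10)
        res = variational_laplace(lambda m: m[0] * t, y, prior,
                                  VLSettings(noise_mode="estimated"))
        assert res.residual_sd == pytest.approx(0.3, rel=0.15)


class TestStepSpecs:
    def test_free_parameter_counts(self):
        # 7 for the single-mechanism models, 10 for the mixture
        assert len(step3_specs("in")) == 7
        assert len(step3_specs("out")) == 7
        assert len(step3_specs("mix")) == 10

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            coupling_specs("bogus")

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ParamSpec("x", -1.0, transform="log")
        with pytest.raises(ValueError):
            ParamSpec("x", 1.5, transform="logit")
        with pytest.raises(ValueError):
            ParamSpec("x", 1.0, transform="weird")


@pytest.fixture(scope="module")
def dataset(truth, small_protocol):
    return generate_synthetic_dataset("in", truth, small_protocol, seed=21)


@pytest.fixture(scope="module")
def step1(dataset):
    return invert_electrical_step1(dataset.eeg, dataset.protocol)


class TestMultiStepPipeline:
    """End-to-end checks on a reduced two-frequency protocol."""

    def test_step1_converges_with_monotone_f(self, step1):
        f = np.array(step1.f_trajectory)
        assert np.all(np.diff(f) >= -1e-9)
        assert step1.n_data == 400  # 2 frequencies x 200 samples

    def test_step2_drive_lengths(self, truth, small_protocol):
        comp = integrate_coupling_step2(truth.electrical, small_protocol)
        for f, c in comp.items():
            assert len(c.a_in) == 306  # 10 Hz x 30.6 s
            assert len(c.v_soma) == 3060  # 100 Hz

    def test_step2_rest_drive_settles_at_baseline(self, small_protocol,
                                                  truth):
        # zero electrical activity: the NO components vanish and the drive
        # reduces to gain * baseline
        import dataclasses
        quiet = dataclasses.replace(truth.electrical, gain1=0.0, gain2=0.0,
                                    gain3=0.0)
        comp = integrate_coupling_step2(quiet, small_protocol)
        for c in comp.values():
            np.testing.assert_allclose(c.a_in, 0.0, atol=1e-12)
            np.testing.assert_allclose(c.v_soma, 0.0, atol=1e-12)

    def test_step3_runs_and_scores_models(self, dataset, step1, truth):
        from levmodel.inversion import _electrical_params
        comp = integrate_coupling_step2(
            _electrical_params(step1.natural_means), dataset.protocol)
        res = invert_hemodynamic_step3(comp, dataset.bold, "in",
                                       dataset.protocol)
        assert np.isfinite(res.free_energy)
        assert res.model_id == "in"
        means = res.natural_means
        assert set(means) == {"kappa", "gamma_fb", "tau_t", "alpha_g", "e0",
                              "baseline", "k_in"}

    def test_cached_step1_gives_identical_step3(self, dataset, step1):
        r1, s1, comp = multistep_invert(dataset, "out", step1_result=step1)
        r2, _, _ = multistep_invert(dataset, "out", step1_result=s1,
                                    step2_components=comp)
        assert r1.free_energy == r2.free_energy
        np.testing.assert_array_equal(r1.posterior.mean, r2.posterior.mean)

    def test_missing_frequencies_rejected(self, dataset, step1):
        with pytest.raises(ValueError):
            invert_hemodynamic_step3({}, dataset.bold, "in",
                                     dataset.protocol)
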