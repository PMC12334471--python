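"""Sampler correctness, determinism, reparameterization and convergence gates."""

import math

import arviz as az
import numpy as np
import pytest

from fishdelt import (
    ModelData,
    ModelSpec,
    ParameterPoint,
    SamplerConfig,
    check_convergence,
    inverse_logit,
    joint_log_density,
    logit,
    sample_posterior,
)
from fishdelt.inference import PosteriorDraws, UnconstrainedPosterior
from fishdelt.nuts import sample_chain

from conftest import random_model_case


def split_rhat_oracle(chains: np.ndarray) -> float:
    """Classic split potential-scale-reduction from the variance-ratio formula."""
    half = chains.shape[1] // 2
    splits = np.concatenate([chains[:, :half], chains[:, half: 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def intercept_data(rng, n=500, p=0.1):
    y = (rng.random(n) < p).astype(float)
    spec = ModelSpec(variant="unconditional")
    data = ModelData(y=y, stream_idx=np.zeros(n, dtype=int), X_stream=np.zeros((1, 0)))
    return spec, data


class TestUnconstrainedPosterior:
    @pytest.mark.parametrize("variant,prior", [
        ("conditional", "horseshoe"), ("conditional", "normal"),
        ("unconditional", "horseshoe"), ("species_specific", "horseshoe"),
    ])
    @pytest.mark.parametrize("parameterization", ["non_centered", "centered"])
    def test_gradient_matches_finite_differences(self, rng, variant, prior, parameterization):
        spec, data, _ = random_model_case(rng, variant=variant, beta_prior=prior)
        post = UnconstrainedPosterior(spec, data, parameterization)
        x = rng.normal(0.0, 0.5, post.dim)
        _, grad = post.logp_grad(x)
        eps = 1e-6
        for i in range(post.dim):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            num = (post.logp_grad(xp)[0] - post.logp_grad(xm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-5)

    @pytest.mark.parametrize("parameterization", ["non_centered", "centered"])
    def test_density_equals_joint_plus_jacobian(self, rng, parameterization):
        """The sampler's target is the declared joint density plus the exact
        log-Jacobian of its reparameterization."""
        spec, data, point = random_model_case(rng, variant="conditional")
        post = UnconstrainedPosterior(spec, data, parameterization)
        # pack the natural point into the unconstrained vector
        x = np.zeros(post.dim)
        x[post.s_b0] = point.beta0
        lt2 = (point.c**2 * point.lam**2) / (point.c**2 + point.tau**2 * point.lam**2)
        m = point.tau * np.sqrt(lt2)
        x[post.s_beta] = point.beta / m
        x[post.s_u] = math.log(point.tau)
        x[post.s_v] = np.log(point.lam)
        x[post.s_w] = math.log(point.c)
        jac = math.log(point.tau) + float(np.sum(np.log(point.lam))) + math.log(point.c)
        jac += float(np.sum(np.log(m)))
        for i, (eff, sigma) in enumerate(
            [(point.gamma, point.sigma_agency), (point.phi, point.sigma_region),
             (point.eta, point.sigma_species)]
        ):
            L = len(eff)
            x[post.s_logsigma[i]] = math.log(sigma)
            jac += math.log(sigma)
            if parameterization == "centered":
                x[post.s_factor[i]] = eff
            else:
                x[post.s_factor[i]] = eff / sigma
                jac += L * math.log(sigma)
        internal, _ = post.logp_grad(x)
        joint = joint_log_density(spec, data, point)
        assert internal == pytest.approx(joint + jac, abs=1e-8)


class TestSampling:
    def test_seed_determinism(self, rng):
        spec, data = intercept_data(rng, n=200)
        cfg = SamplerConfig(chains=2, warmup=100, draws=100, seed=99)
        a = sample_posterior(spec, data, cfg)
        b = sample_posterior(spec, data, cfg)
        np.testing.assert_array_equal(a.stacked("beta0"), b.stacked("beta0"))
        c = sample_posterior(spec, data, SamplerConfig(chains=2, warmup=100, draws=100, seed=100))
        assert not np.array_equal(a.stacked("beta0"), c.stacked("beta0"))

    def test_intercept_recovery_half(self, rng):
        """Balanced Bernoulli data recover an occurrence probability of 0.5."""
        n = 2000
        y = np.zeros(n)
        y[: n // 2] = 1.0
        spec = ModelSpec(variant="unconditional")
        data = ModelData(y=y, stream_idx=np.zeros(n, dtype=int), X_stream=np.zeros((1, 0)))
        draws = sample_posterior(spec, data, SamplerConfig(chains=2, warmup=300, draws=500, seed=4))
        p = inverse_logit(draws.stacked("beta0"))
        assert abs(p.mean() - 0.5) < 0.03

    def test_requested_draw_shape(self, rng):
        spec, data = intercept_data(rng, n=100)
        draws = sample_posterior(spec, data, SamplerConfig(chains=3, warmup=50, draws=60, seed=1))
        assert draws.params["beta0"].shape == (3, 60)

    def test_all_zero_outcomes_warns(self, rng, caplog):
        spec = ModelSpec(variant="unconditional")
        data = ModelData(y=np.zeros(80), stream_idx=np.zeros(80, dtype=int),
                         X_stream=np.zeros((1, 0)))
        with caplog.at_level("WARNING", logger="fishdelt.inference"):
            draws = sample_posterior(spec, data, SamplerConfig(chains=2, warmup=100, draws=50, seed=2))
        assert "constant" in caplog.text
        assert draws.params["beta0"].shape == (2, 50)

    def test_parameterization_equivalence(self, rng):
        """Centered and non-centered runs target the same posterior."""
        cfg = dict(n_species=6, n_agencies=3, n_ecoregions=3)
        from fishdelt.simulate import GeneratorConfig, simulate_delt_dataset
        from fishdelt.estimators import make_model_data

        gen = GeneratorConfig(**cfg, n_streams=60, n_predictors=1,
                              fish_per_stream_mean=40, beta0=logit(0.15),
                              sigma_agency=0.4, sigma_region=0.3, sigma_species=0.4, seed=8)
        obs, _, _ = simulate_delt_dataset(gen)
        data, levels = make_model_data(
            obs.delt.to_numpy(), None, agency=obs.agency, ecoregion=obs.ecoregion,
            species=obs.species,
        )
        spec = ModelSpec(variant="unconditional", agencies=levels["agency"],
                         ecoregions=levels["ecoregion"], species=levels["species"])
        out = {}
        for param in ("non_centered", "centered"):
            d = sample_posterior(
                spec, data,
                SamplerConfig(chains=2, warmup=400, draws=600, seed=5, parameterization=param),
            )
            b0 = d.stacked("beta0")
            ess = float(az.ess(az.convert_to_dataset(d.params["beta0"]))["x"].item())
            out[param] = (b0.mean(), b0.std() / math.sqrt(max(ess, 10.0)))
        gap = abs(out["centered"][0] - out["non_centered"][0])
        se = math.hypot(out["centered"][1], out["non_centered"][1])
        assert gap < 4 * se

    def test_positive_scales(self, rng):
        spec, data, _ = random_model_case(rng, n=60)
        draws = sample_posterior(spec, data, SamplerConfig(chains=2, warmup=150, draws=100, seed=3))
        for name in ("sigma_agency", "sigma_region", "sigma_species", "tau", "c"):
            assert np.all(draws.stacked(name) > 0)
        assert np.all(draws.stacked("lam") > 0)

    def test_save_load_round_trip(self, rng, tmp_path):
        spec, data = intercept_data(rng, n=100)
        draws = sample_posterior(spec, data, SamplerConfig(chains=2, warmup=50, draws=40, seed=6))
        path = tmp_path / "draws.npz"
        draws.save(path)
        back = PosteriorDraws.load(path)
        for k, v in draws.params.items():
            np.testing.assert_array_equal(back.params[k], v)
        assert back.spec == spec
        assert back.config == draws.config


class TestConvergence:
    def _fake_draws(self, arrays):
        spec = ModelSpec(variant="unconditional")
        cfg = SamplerConfig(chains=arrays["beta0"].shape[0], warmup=0,
                            draws=arrays["beta0"].shape[1], seed=0)
        C, D = arrays["beta0"].shape[:2]
        return PosteriorDraws(
            params=arrays, coords={}, spec=spec, config=cfg,
            divergent=np.zeros((C, D), dtype=bool),
            step_sizes=np.ones(C), accept_means=np.ones(C),
        )

    def test_well_mixed_chains_pass(self, rng):
        draws = self._fake_draws({"beta0": rng.standard_normal((2, 1000))})
        report = check_convergence(draws)
        assert report.passed
        rhat = report.table["rhat"].iloc[0]
        assert 0.99 <= rhat <= 1.02

    def test_offset_chains_fail(self, rng):
        arr = rng.standard_normal((2, 1000))
        arr[1] += 10.0
        report = check_convergence(self._fake_draws({"beta0": arr}))
        assert not report.passed
        assert report.table["rhat"].iloc[0] > 1.5

    def test_rhat_matches_variance_ratio_oracle(self, rng):
        arr = rng.standard_normal((4, 500)) + rng.normal(0, 0.05, size=(4, 1))
        report = check_convergence(self._fake_draws({"beta0": arr}))
        assert report.table["rhat"].iloc[0] == pytest.approx(split_rhat_oracle(arr), abs=1e-8)

    def test_single_chain_rejected(self, rng):
        spec = ModelSpec(variant="unconditional")
        with pytest.raises(ValueError):
            SamplerConfig(chains=1, warmup=10, draws=10, seed=0)
        draws = self._fake_draws({"beta0": rng.standard_normal((2, 50))})
        draws.params["beta0"] = draws.params["beta0"][:1]
        draws.divergent = draws.divergent[:1]
        with pytest.raises(ValueError, match="chains"):
            check_convergence(draws)

    def test_divergences_fail_but_flagging_keeps_draws(self, rng):
        draws = self._fake_draws({"beta0": rng.standard_normal((2, 1000))})
        draws.divergent[0, 0] = True
        report = check_convergence(draws)
        assert not report.passed and "divergent" in " ".join(report.reasons)
        assert draws.params["beta0"].shape == (2, 1000)


class TestNutsOnKnownTargets:
    def test_correlated_gaussian_moments(self):
        cov = np.array([[2.0, 0.9], [0.9, 1.0]])
        prec = np.linalg.inv(cov)

        def lg(x):
            return -0.5 * float(x @ prec @ x), -prec @ x

        res = sample_chain(lg, np.zeros(2), 500, 4000, np.random.default_rng(12),
                           target_accept=0.9)
        est = np.cov(res.draws.T)
        assert np.abs(res.draws.mean(axis=0)).max() < 0.12
        assert np.abs(est - cov).max() < 0.25
        assert res.divergences == 0

    def test_grid_oracle_bernoulli_intercept(self, rng):
        """Posterior mean of the occurrence probability matches dense numeric
        integration of the exact 1-D posterior."""
        spec, data = intercept_data(rng, n=400, p=0.15)
        draws = sample_posterior(spec, data, SamplerConfig(chains=2, warmup=400, draws=1000, seed=7))
        p = inverse_logit(draws.stacked("beta0"))
        grid = np.linspace(-9.0, 3.0, 8001)
        loglik = data.y.sum() * grid - data.n_obs * np.logaddexp(0.0, grid)
        logpost = loglik - 0.5 * (grid / 5.0) ** 2
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        oracle_mean = float(w @ inverse_logit(grid))
        ess = float(az.ess(az.convert_to_dataset(
            inverse_logit(draws.params["beta0"])))["x"].item())
        mc_se = p.std() / math.sqrt(max(ess, 10.0))
        assert abs(p.mean() - oracle_mean) < 3 * mc_se + 1e-4
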