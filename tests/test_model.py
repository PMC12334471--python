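"""Model-spec contracts and joint log-density correctness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fishdelt import (
    ModelData,
    ModelSpec,
    ParameterPoint,
    SpecError,
    build_spec,
    horseshoe_shrunk_scale,
    inverse_logit,
    joint_log_density,
    logit,
)
from fishdelt.errors import ShapeError

from conftest import random_model_case


def naive_joint_log_density(spec, data, point):
    """Per-observation / per-prior-term summation with textbook densities."""
    total = 0.0
    for i in range(data.n_obs):
        lp = point.beta0
        if spec.n_predictors:
            lp += float(data.X_stream[data.stream_idx[i]] @ np.asarray(point.beta))
        if spec.agencies:
            lp += point.gamma[data.agency_idx[i]]
        if spec.ecoregions:
            lp += point.phi[data.region_idx[i]]
        if spec.species:
            lp += point.eta[data.species_idx[i]]
        total += stats.bernoulli.logpmf(data.y[i], 1.0 / (1.0 + math.exp(-lp)))
    total += stats.norm.logpdf(point.beta0, 0.0, spec.intercept_scale)
    for eff, sigma, levels in (
        (point.gamma, point.sigma_agency, spec.agencies),
        (point.phi, point.sigma_region, spec.ecoregions),
        (point.eta, point.sigma_species, spec.species),
    ):
        if levels:
            total += sum(stats.norm.logpdf(e, 0.0, sigma) for e in eff)
            total += stats.halfcauchy.logpdf(sigma, scale=spec.sigma_scale)
    if spec.n_predictors:
        if spec.beta_prior == "normal":
            total += sum(stats.norm.logpdf(b, 0.0, spec.beta_scale) for b in point.beta)
        else:
            for f in range(spec.n_predictors):
                lt2 = (point.c**2 * point.lam[f] ** 2) / (
                    point.c**2 + point.tau**2 * point.lam[f] ** 2
                )
                total += stats.norm.logpdf(point.beta[f], 0.0, point.tau * math.sqrt(lt2))
                total += stats.halfcauchy.logpdf(point.lam[f], scale=1.0)
            total += stats.halfcauchy.logpdf(
                point.tau, scale=spec.resolve_global_scale(data.n_obs)
            )
            alpha = spec.slab_df / 2.0
            b = spec.slab_df * spec.slab_scale**2 / 2.0
            total += stats.invgamma.logpdf(point.c**2, alpha, scale=b) + math.log(2 * point.c)
    return float(total)


class TestInverseLogit:
    def test_symmetry(self):
        assert inverse_logit(0.0) == 0.5
        for x in (-3.0, -0.7, 1.2, 8.0):
            assert inverse_logit(x) + inverse_logit(-x) == pytest.approx(1.0)

    def test_population_average_scale(self):
        # the logit value that maps to the 2% occurrence-probability scale
        assert inverse_logit(-3.8918) == pytest.approx(0.020, abs=5e-4)

    def test_strictly_increasing_and_inverts_logit(self):
        grid = np.linspace(0.001, 0.999, 101)
        back = inverse_logit(logit(grid))
        np.testing.assert_allclose(back, grid, atol=1e-12)
        vals = inverse_logit(np.linspace(-30, 30, 1001))
        assert np.all(np.diff(vals) > 0)

    def test_extreme_arguments_stable(self):
        assert inverse_logit(-800.0) == 0.0
        assert inverse_logit(800.0) == 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            inverse_logit(float("nan"))


class TestHorseshoeScale:
    def test_unit_case(self):
        assert horseshoe_shrunk_scale(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_hand_evaluated(self):
        assert horseshoe_shrunk_scale(2.0, 3.0, 1.0) == pytest.approx(9.0 / 37.0)

    def test_slab_dominated_limit(self):
        lam = 3.0
        val = horseshoe_shrunk_scale(0.7, lam, 1e6)
        assert abs(val - lam**2) / lam**2 < 1e-6

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(1e-3, 1e3), st.floats(1e-3, 1e3), st.floats(1e-3, 1e3)
    )
    def test_algebraic_bound(self, tau, lam, c):
        val = horseshoe_shrunk_scale(tau, lam, c)
        assert val <= min(lam**2, (c / tau) ** 2) * (1 + 1e-12)

    def test_positivity_required(self):
        with pytest.raises(ValueError):
            horseshoe_shrunk_scale(-1.0, 1.0, 1.0)


class TestBuildSpec:
    def test_unconditional_counts(self):
        spec = build_spec(
            "unconditional",
            agencies=[f"a{i}" for i in range(7)],
            ecoregions=[f"e{i}" for i in range(9)],
            species=[f"s{i}" for i in range(57)],
        )
        assert spec.n_predictors == 0
        assert len(spec.agencies) == 7 and len(spec.ecoregions) == 9 and len(spec.species) == 57

    def test_conditional_carries_horseshoe_coefficients(self):
        spec = build_spec(
            "conditional",
            agencies=["a"], ecoregions=["e"], species=["s"],
            predictors=[f"p{i}" for i in range(46)],
        )
        assert spec.n_predictors == 46 and spec.beta_prior == "horseshoe"

    def test_species_specific_drops_species_factor(self):
        spec = build_spec(
            "species_specific",
            agencies=["a"], ecoregions=["e"], species=["rock bass"], predictors=["p"],
        )
        assert spec.species == ()

    def test_species_specific_multispecies_rejected(self):
        with pytest.raises(SpecError, match="subset"):
            build_spec(
                "species_specific",
                agencies=["a"], ecoregions=["e"], species=["s1", "s2"], predictors=["p"],
            )

    def test_global_scale_default(self):
        spec = build_spec(
            "conditional", agencies=["a"], ecoregions=["e"], species=["s"],
            predictors=[f"p{i}" for i in range(30)], p0=5.0,
        )
        assert spec.resolve_global_scale(10_000) == pytest.approx(5.0 / (25.0 * 100.0))


class TestJointLogDensity:
    def test_single_observation_intercept_only(self):
        spec = ModelSpec(variant="unconditional")
        data = ModelData(y=[1.0], stream_idx=[0], X_stream=np.zeros((1, 0)))
        point = ParameterPoint(beta0=0.0)
        val = joint_log_density(spec, data, point)
        prior = stats.norm.logpdf(0.0, 0.0, spec.intercept_scale)
        assert val == pytest.approx(math.log(0.5) + prior, abs=1e-12)

    @pytest.mark.parametrize("variant", ["unconditional", "conditional", "species_specific"])
    @pytest.mark.parametrize("beta_prior", ["horseshoe", "normal"])
    def test_matches_naive_summation_oracle(self, rng, variant, beta_prior):
        for _ in range(3):
            spec, data, point = random_model_case(rng, variant=variant, beta_prior=beta_prior)
            got = joint_log_density(spec, data, point)
            want = naive_joint_log_density(spec, data, point)
            assert got == pytest.approx(want, abs=1e-10)

    def test_nonconforming_point_rejected(self, rng):
        spec = ModelSpec(variant="unconditional", agencies=("a",), ecoregions=("e",),
                         species=("s",))
        data = ModelData(y=[1.0, 0.0], stream_idx=[0, 0], X_stream=np.zeros((1, 0)),
                         agency_idx=[0, 0], region_idx=[0, 0], species_idx=[0, 0])
        bad = ParameterPoint(beta0=0.0, beta=np.array([0.5]), gamma=np.zeros(1),
                             phi=np.zeros(1), eta=np.zeros(1), sigma_agency=1.0,
                             sigma_region=1.0, sigma_species=1.0)
        with pytest.raises(SpecError):
            joint_log_density(spec, data, bad)

    def test_misaligned_dimensions_rejected(self, rng):
        spec, data, point = random_model_case(rng)
        bad_data = ModelData(
            y=data.y, stream_idx=data.stream_idx,
            X_stream=data.X_stream[:, :2],
            agency_idx=data.agency_idx, region_idx=data.region_idx,
            species_idx=data.species_idx,
        )
        with pytest.raises(ShapeError):
            joint_log_density(spec, bad_data, point)

    def test_flipping_concordant_outcome_lowers_density(self, rng):
        """Flipping one y against a strongly concordant linear predictor
        must reduce the likelihood term."""
        spec, data, point = random_model_case(rng, variant="unconditional", P=0)
        point = ParameterPoint(
            beta0=4.0, gamma=point.gamma * 0, phi=point.phi * 0, eta=point.eta * 0,
            sigma_agency=1.0, sigma_region=1.0, sigma_species=1.0,
        )
        y = np.ones_like(data.y)
        concordant = ModelData(y=y, stream_idx=data.stream_idx, X_stream=data.X_stream,
                               agency_idx=data.agency_idx, region_idx=data.region_idx,
                               species_idx=data.species_idx)
        y_flip = y.copy()
        y_flip[0] = 0.0
        flipped = ModelData(y=y_flip, stream_idx=data.stream_idx, X_stream=data.X_stream,
                            agency_idx=data.agency_idx, region_idx=data.region_idx,
                            species_idx=data.species_idx)
        assert joint_log_density(spec, flipped, point) < joint_log_density(spec, concordant, point)

    def test_tiny_sigma_reduces_to_intercept_likelihood(self, rng):
        """With random effects pinned at 0 and tiny sigmas, differences in
        the joint density across intercepts equal differences of the
        intercept-only Bernoulli log-likelihood."""
        spec, data, _ = random_model_case(rng, variant="unconditional", P=0)

        def at(b0):
            point = ParameterPoint(
                beta0=b0,
                gamma=np.zeros(len(spec.agencies)), phi=np.zeros(len(spec.ecoregions)),
                eta=np.zeros(len(spec.species)),
                sigma_agency=1e-6, sigma_region=1e-6, sigma_species=1e-6,
            )
            return joint_log_density(spec, data, point)

        def intercept_loglik(b0):
            p = inverse_logit(b0)
            k = data.y.sum()
            n = data.n_obs
            return k * math.log(p) + (n - k) * math.log(1 - p)

        lhs = at(0.7) - at(-0.9)
        prior_diff = stats.norm.logpdf(0.7, 0, 5) - stats.norm.logpdf(-0.9, 0, 5)
        rhs = intercept_loglik(0.7) - intercept_loglik(-0.9) + prior_diff
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestSpecValidation:
    def test_unconditional_rejects_predictors(self):
        with pytest.raises(SpecError):
            ModelSpec(variant="unconditional", predictors=("p",))

    def test_species_specific_rejects_species(self):
        with pytest.raises(SpecError):
            ModelSpec(variant="species_specific", species=("s",))

    def test_hyperparameters_positive(self):
        with pytest.raises(SpecError):
            ModelSpec(variant="conditional", predictors=("p",), slab_scale=-1.0)
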