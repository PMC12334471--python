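"""Hierarchical Bayesian occurrence models for binary DELT outcomes.

Three logit-linear model variants share one structure. For fish *i* in
stream *j*, collected by agency *k* in ecoregion *r*, of species *s*:

    Pr(y = 1) = logit^-1(beta0 + X_j beta + gamma_k + phi_r + eta_s)

with crossed normal random effects gamma_k ~ N(0, sigma_agency^2),
phi_r ~ N(0, sigma_region^2), eta_s ~ N(0, sigma_species^2):

- ``unconditional``   — no landscape predictors (beta absent); used for
  species/agency/ecoregion occurrence probabilities and the
  population-average probability logit^-1(beta0).
- ``conditional``     — adds the standardized landscape predictor matrix X
  with a regularized horseshoe prior on beta for sparse selection.
- ``species_specific``— the conditional model fitted to one species'
  data, with the species random effect removed.

The regularized horseshoe prior on each coefficient beta_f is

    beta_f ~ N(0, tau^2 * lambda_tilde_f^2),
    lambda_tilde_f^2 = c^2 lambda_f^2 / (c^2 + tau^2 lambda_f^2)

with global scale tau ~ half-Cauchy(tau0), local scales
lambda_f ~ half-Cauchy(1) and slab c^2 ~ Inv-Gamma(df/2, df*s^2/2). Small
tau*lambda_f shrinks a coefficient toward zero; the slab scale s bounds
coefficients that escape shrinkage. The default global-scale
tau0 = p0 / ((P - p0) sqrt(n)) encodes a prior guess of p0 nonzero
coefficients among P.

Random effects are mean-zero by prior only (no sum-to-zero constraint);
year is carried as observation metadata but not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ShapeError, SpecError

VARIANTS = ("unconditional", "conditional", "species_specific")

LOG_2_PI = math.log(2.0 * math.pi)


def inverse_logit(x):
    """Numerically stable logistic function 1 / (1 + exp(-x)).

    Evaluated via exp(-|x|) so neither branch overflows; strictly
    monotone. Scalar or array input; non-finite input is rejected.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("inverse_logit requires finite input")
    e = np.exp(-np.abs(arr))
    out = np.where(arr >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def logit(p):
    p = np.asarray(p, dtype=float)
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def horseshoe_shrunk_scale(tau, lam, c):
    """Regularized local scale: lambda_tilde^2 = c^2 lam^2 / (c^2 + tau^2 lam^2).

    The effective prior SD of a coefficient is tau * lambda_tilde. For
    small tau*lam the value approaches lam^2 (pure horseshoe); for large
    tau*lam it saturates at c^2 / tau^2 so the implied coefficient scale
    is capped by the slab at c.
    """
    tau_a, lam_a, c_a = (np.asarray(v, dtype=float) for v in (tau, lam, c))
    if np.any(tau_a <= 0) or np.any(lam_a <= 0) or np.any(c_a <= 0):
        raise ValueError("tau, lambda and c must be positive")
    if not (np.all(np.isfinite(tau_a)) and np.all(np.isfinite(lam_a)) and np.all(np.isfinite(c_a))):
        raise ValueError("tau, lambda and c must be finite")
    out = (c_a**2 * lam_a**2) / (c_a**2 + tau_a**2 * lam_a**2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModelSpec:
    """Which model variant to fit, over which factor levels and predictors.

    Factor levels are label tuples; an empty tuple means the factor is
    absent from the linear predictor (the species-specific variant drops
    the species factor). ``beta_prior`` is ``"horseshoe"`` (the default
    for any spec with predictors) or ``"normal"`` (independent
    N(0, beta_scale^2), a non-sparse reference prior).
    """

    variant: str
    agencies: tuple[str, ...] = ()
    ecoregions: tuple[str, ...] = ()
    species: tuple[str, ...] = ()
    predictors: tuple[str, ...] = ()
    beta_prior: str = "horseshoe"
    intercept_scale: float = 5.0
    sigma_scale: float = 2.5
    p0: float = 5.0
    slab_scale: float = 2.0
    slab_df: float = 4.0
    global_scale: float | None = None
    beta_scale: float = 5.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise SpecError(f"unknown variant {self.variant!r}")
        if self.variant == "unconditional" and self.predictors:
            raise SpecError("the unconditional model has no predictors")
        if self.variant == "species_specific" and self.species:
            raise SpecError("the species-specific model has no species random effect")
        if self.beta_prior not in ("horseshoe", "normal"):
            raise SpecError(f"beta_prior must be horseshoe or normal, got {self.beta_prior!r}")
        for name in ("intercept_scale", "sigma_scale", "p0", "slab_scale", "slab_df", "beta_scale"):
            if getattr(self, name) <= 0:
                raise SpecError(f"hyperparameter {name} must be strictly positive")
        if self.global_scale is not None and self.global_scale <= 0:
            raise SpecError("global_scale must be strictly positive")

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)

    @property
    def factors(self) -> dict[str, tuple[str, ...]]:
        return {"agency": self.agencies, "ecoregion": self.ecoregions, "species": self.species}

    def resolve_global_scale(self, n_obs: int) -> float:
        """tau0, defaulting to p0 / ((P - p0) sqrt(n))."""
        if self.global_scale is not None:
            return self.global_scale
        P = self.n_predictors
        if P <= self.p0:
            return 1.0 / math.sqrt(n_obs)
        return self.p0 / ((P - self.p0) * math.sqrt(n_obs))


def build_spec(
    variant: str,
    *,
    agencies: Sequence[str],
    ecoregions: Sequence[str],
    species: Sequence[str] = (),
    predictors: Sequence[str] = (),
    **hyper,
) -> ModelSpec:
    """Construct one of the three canonical model variants.

    Enforces the variant contracts: the unconditional and conditional
    models include all three crossed random effects; the species-specific
    model must be built for a single species' data (pass that one label;
    the factor itself is then dropped).
    """
    if variant not in VARIANTS:
        raise SpecError(f"unknown variant {variant!r}")
    agencies = tuple(agencies)
    ecoregions = tuple(ecoregions)
    species = tuple(species)
    predictors = tuple(predictors)
    if not agencies or not ecoregions:
        raise SpecError("agency and ecoregion factor levels must be non-empty")
    if variant == "unconditional":
        if predictors:
            raise SpecError("the unconditional model takes no predictors")
        if not species:
            raise SpecError("the unconditional model needs species levels")
    if variant == "conditional":
        if not species:
            raise SpecError("the conditional model needs species levels")
        if not predictors:
            raise SpecError("the conditional model needs at least one predictor")
    if variant == "species_specific":
        if len(species) > 1:
            raise SpecError(
                "species-specific model requested with multi-species data: "
                "subset the observations to one species and fit per species"
            )
        species = ()
        if not predictors:
            raise SpecError("the species-specific model needs at least one predictor")
    return ModelSpec(
        variant=variant,
        agencies=agencies,
        ecoregions=ecoregions,
        species=species,
        predictors=predictors,
        **hyper,
    )


@dataclass(frozen=True)
class ParameterPoint:
    """One point in parameter space, on the natural (constrained) scale.

    Blocks that a spec excludes are ``None``. Scale parameters must be
    strictly positive; horseshoe blocks (tau, lam, c) are present iff the
    spec uses the horseshoe prior.
    """

    beta0: float
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    phi: np.ndarray | None = None
    eta: np.ndarray | None = None
    sigma_agency: float | None = None
    sigma_region: float | None = None
    sigma_species: float | None = None
    tau: float | None = None
    lam: np.ndarray | None = None
    c: float | None = None

    def validate(self, spec: ModelSpec) -> None:
        def _block(name, value, n_expected):
            if n_expected == 0:
                if value is not None and np.size(value) > 0 and np.any(np.asarray(value) != 0):
                    raise SpecError(f"spec excludes {name} but a nonzero block was supplied")
                return
            if value is None or np.shape(np.atleast_1d(value)) != (n_expected,):
                raise SpecError(f"{name} must have length {n_expected}")

        _block("beta", self.beta, spec.n_predictors)
        _block("gamma", self.gamma, len(spec.agencies))
        _block("phi", self.phi, len(spec.ecoregions))
        _block("eta", self.eta, len(spec.species))
        for name, sigma, levels in (
            ("sigma_agency", self.sigma_agency, spec.agencies),
            ("sigma_region", self.sigma_region, spec.ecoregions),
            ("sigma_species", self.sigma_species, spec.species),
        ):
            if levels:
                if sigma is None or sigma <= 0:
                    raise SpecError(f"{name} must be a positive scalar")
        if spec.n_predictors and spec.beta_prior == "horseshoe":
            if self.tau is None or self.tau <= 0 or self.c is None or self.c <= 0:
                raise SpecError("horseshoe prior requires positive tau and c")
            _block("lam", self.lam, spec.n_predictors)
            if np.any(np.asarray(self.lam) <= 0):
                raise SpecError("local scales lam must be positive")
        elif self.tau is not None or self.lam is not None or self.c is not None:
            raise SpecError("tau/lam/c are only defined under the horseshoe prior")


@dataclass
class ModelData:
    """Observation-aligned arrays consumed by the likelihood.

    ``X_stream`` holds one row of standardized predictors per distinct
    stream; ``stream_idx`` maps each fish onto its row. Factor index
    arrays map each fish onto the spec's level tuples. For the
    unconditional model ``X_stream`` may have zero columns.
    """

    y: np.ndarray
    stream_idx: np.ndarray
    X_stream: np.ndarray
    agency_idx: np.ndarray | None = None
    region_idx: np.ndarray | None = None
    species_idx: np.ndarray | None = None
    stream_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.stream_idx = np.asarray(self.stream_idx, dtype=np.int64)
        self.X_stream = np.atleast_2d(np.asarray(self.X_stream, dtype=float))
        if self.X_stream.size == 0:
            self.X_stream = np.zeros((max(int(self.stream_idx.max(initial=-1)) + 1, 1), 0))
        n = self.y.shape[0]
        if self.stream_idx.shape != (n,):
            raise ShapeError("stream_idx must align with y")
        for name in ("agency_idx", "region_idx", "species_idx"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64)
                if v.shape != (n,):
                    raise ShapeError(f"{name} must align with y")
                setattr(self, name, v)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be binary")
        if self.stream_idx.min(initial=0) < 0 or self.stream_idx.max(initial=0) >= self.X_stream.shape[0]:
            raise ShapeError("stream_idx out of range of X_stream rows")

    @property
    def n_obs(self) -> int:
        return int(self.y.shape[0])

    @property
    def n_predictors(self) -> int:
        return int(self.X_stream.shape[1])

    def validate(self, spec: ModelSpec) -> None:
        if spec.n_predictors != self.n_predictors:
            raise ShapeError(
                f"spec has {spec.n_predictors} predictors but data has {self.n_predictors}"
            )
        for name, idx, levels in (
            ("agency", self.agency_idx, spec.agencies),
            ("ecoregion", self.region_idx, spec.ecoregions),
            ("species", self.species_idx, spec.species),
        ):
            if levels:
                if idx is None:
                    raise ShapeError(f"spec includes the {name} factor but data has no index")
                if idx.max(initial=0) >= len(levels) or idx.min(initial=0) < 0:
                    raise ShapeError(f"{name} index out of range for {len(levels)} levels")


def _log_half_cauchy(x: float, scale: float) -> float:
    """log density of a half-Cauchy(scale) variate at x > 0."""
    return math.log(2.0 / (math.pi * scale)) - math.log1p((x / scale) ** 2)


def _log_inv_gamma(x: float, alpha: float, beta: float) -> float:
    return alpha * math.log(beta) - math.lgamma(alpha) - (alpha + 1.0) * math.log(x) - beta / x


def linear_predictor(spec: ModelSpec, data: ModelData, point: ParameterPoint) -> np.ndarray:
    """Per-observation logit-scale mean implied by the variant."""
    lp = np.full(data.n_obs, float(point.beta0))
    if spec.n_predictors:
        lp += (data.X_stream @ np.asarray(point.beta, dtype=float))[data.stream_idx]
    if spec.agencies:
        lp += np.asarray(point.gamma, dtype=float)[data.agency_idx]
    if spec.ecoregions:
        lp += np.asarray(point.phi, dtype=float)[data.region_idx]
    if spec.species:
        lp += np.asarray(point.eta, dtype=float)[data.species_idx]
    return lp


def joint_log_density(spec: ModelSpec, data: ModelData, point: ParameterPoint) -> float:
    """Joint log density log p(y, parameters) for a model variant.

    Bernoulli log-likelihood at the variant's linear predictor, plus
    N(0, sigma_x^2) log-priors on each included random-effect block,
    half-Cauchy(sigma_scale) log-priors on the sigma's, a
    N(0, intercept_scale^2) prior on beta0, and the fixed-effect prior:
    the regularized horseshoe (including the tau, lambda and c^2
    hyperpriors, with the density expressed in c) or independent normals.
    Normalizing constants are included, so the value matches a per-term
    textbook-density summation exactly.
    """
    point.validate(spec)
    data.validate(spec)

    lp = linear_predictor(spec, data, point)
    # Bernoulli: y*lp - log(1 + exp(lp)), stable softplus
    loglik = float(np.sum(data.y * lp) - np.sum(np.logaddexp(0.0, lp)))

    out = loglik
    out += -0.5 * LOG_2_PI - math.log(spec.intercept_scale) - 0.5 * (
        point.beta0 / spec.intercept_scale
    ) ** 2

    for effect, sigma, levels in (
        (point.gamma, point.sigma_agency, spec.agencies),
        (point.phi, point.sigma_region, spec.ecoregions),
        (point.eta, point.sigma_species, spec.species),
    ):
        if levels:
            g = np.asarray(effect, dtype=float)
            out += float(
                -0.5 * len(levels) * LOG_2_PI
                - len(levels) * math.log(sigma)
                - 0.5 * np.sum((g / sigma) ** 2)
            )
            out += _log_half_cauchy(sigma, spec.sigma_scale)

    if spec.n_predictors:
        beta = np.asarray(point.beta, dtype=float)
        if spec.beta_prior == "normal":
            out += float(
                -0.5 * spec.n_predictors * LOG_2_PI
                - spec.n_predictors * math.log(spec.beta_scale)
                - 0.5 * np.sum((beta / spec.beta_scale) ** 2)
            )
        else:
            lam = np.asarray(point.lam, dtype=float)
            lt2 = horseshoe_shrunk_scale(point.tau, lam, point.c)
            sd = point.tau * np.sqrt(lt2)
            out += float(-0.5 * spec.n_predictors * LOG_2_PI - np.sum(np.log(sd)) - 0.5 * np.sum((beta / sd) ** 2))
            tau0 = spec.resolve_global_scale(data.n_obs)
            out += _log_half_cauchy(point.tau, tau0)
            out += float(np.sum([_log_half_cauchy(lv, 1.0) for lv in lam]))
            # slab: c^2 ~ Inv-Gamma(df/2, df*s^2/2), density expressed in c
            alpha = spec.slab_df / 2.0
            b = spec.slab_df * spec.slab_scale**2 / 2.0
            out += _log_inv_gamma(point.c**2, alpha, b) + math.log(2.0 * point.c)

    if not math.isfinite(out):
        raise ValueError("joint log density is not finite at this point")
    return out
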