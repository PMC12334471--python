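"""Synthetic fish-community DELT datasets with known ground truth.

The generator draws data from exactly the generative model the analysis
assumes: streams carry multivariate-normal landscape predictors, crossed
normal random effects act per agency / ecoregion / species, a sparse
coefficient vector links predictors to the logit of occurrence, and each
fish's binary DELT outcome is Bernoulli at its stream/species linear
predictor. Every sampled quantity is recorded in a :class:`GroundTruth`
so parameter-recovery tests can compare fitted posteriors against truth.

:func:`study_mimic_config` mirrors the scale of a regional survey of the
Chesapeake Bay watershed — 57 species, 7 agencies, 9 ecoregions, 1,196
streams, 46 predictors, overall prevalence near 1.4%, heavily skewed
per-stream and per-species sample sizes — scaled down about 20x by
default so a desk-size integration run stays cheap. It reproduces the
statistical structure, not any real landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import inverse_logit


@dataclass(frozen=True)
class GeneratorConfig:
    """True parameter values and design counts for one synthetic dataset."""

    n_species: int = 10
    n_agencies: int = 4
    n_ecoregions: int = 3
    n_streams: int = 100
    n_predictors: int = 5
    fish_per_stream_mean: float = 30.0
    fish_per_stream_size: float = 1.0   # negative-binomial size; smaller = more skew
    beta0: float = -3.0
    beta: tuple[float, ...] = ()        # padded with zeros to n_predictors
    sigma_agency: float = 0.0
    sigma_region: float = 0.0
    sigma_species: float = 0.0
    predictor_correlation: str = "independent"  # or "collinear_pair"
    collinear_rho: float = 0.95
    species_abundance_sd: float = 1.0
    species_inclusion: tuple[float, float] = (1.5, 5.0)  # Beta(a, b) stream-inclusion probs
    year_range: tuple[int, int] = (2008, 2019)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_species", "n_agencies", "n_ecoregions", "n_streams", "n_predictors"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("sigma_agency", "sigma_region", "sigma_species"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if len(self.beta) > self.n_predictors:
            raise ConfigError("beta longer than the number of predictors")
        if self.predictor_correlation not in ("independent", "collinear_pair"):
            raise ConfigError(f"unknown predictor correlation {self.predictor_correlation!r}")
        if not 0 < self.collinear_rho < 1:
            raise ConfigError("collinear_rho must be in (0, 1)")
        if self.fish_per_stream_mean <= 0 or self.fish_per_stream_size <= 0:
            raise ConfigError("fish-per-stream parameters must be positive")

    @property
    def beta_full(self) -> np.ndarray:
        out = np.zeros(self.n_predictors)
        out[: len(self.beta)] = self.beta
        return out

    def labels(self) -> dict[str, list[str]]:
        return {
            "species": [f"sp{i+1:02d}" for i in range(self.n_species)],
            "agency": [f"agency{i+1}" for i in range(self.n_agencies)],
            "ecoregion": [f"eco{i+1}" for i in range(self.n_ecoregions)],
            "stream": [f"comid{i+1:05d}" for i in range(self.n_streams)],
            "predictor": [f"pred{i+1:02d}" for i in range(self.n_predictors)],
        }


@dataclass
class GroundTruth:
    """Everything the generator sampled, for recovery checks."""

    beta0: float
    beta: pd.Series
    gamma: pd.Series
    phi: pd.Series
    eta: pd.Series
    sigma_agency: float
    sigma_region: float
    sigma_species: float
    stream_lp: pd.Series            # beta0 + X beta per stream
    config: GeneratorConfig

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta": self.beta.to_dict(),
            "gamma": self.gamma.to_dict(),
            "phi": self.phi.to_dict(),
            "eta": self.eta.to_dict(),
            "sigma_agency": self.sigma_agency,
            "sigma_region": self.sigma_region,
            "sigma_species": self.sigma_species,
            "stream_lp": self.stream_lp.to_dict(),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
        }


def generate_predictor_matrix(config: GeneratorConfig) -> pd.DataFrame:
    """Stream x predictor table of correlated standard-normal draws.

    With ``predictor_correlation="collinear_pair"`` the first two columns
    get correlation ``collinear_rho`` so the Spearman screen has a
    designed positive case; otherwise columns are independent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    labels = config.labels()
    P = config.n_predictors
    corr = np.eye(P)
    if config.predictor_correlation == "collinear_pair":
        if P < 2:
            raise ConfigError("collinear_pair needs at least 2 predictors")
        corr[0, 1] = corr[1, 0] = config.collinear_rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by config checks
        raise ConfigError("predictor correlation matrix is not positive definite") from exc
    z = rng.standard_normal((config.n_streams, P))
    vals = z @ chol.T
    return pd.DataFrame(vals, index=pd.Index(labels["stream"], name="stream_id"),
                        columns=labels["predictor"])


def simulate_delt_dataset(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one complete synthetic survey.

    Returns (observations, predictor table, ground truth). Streams are
    assigned one agency and one ecoregion each; per-stream fish counts are
    negative-binomial (zero-truncated) to mimic the heavy skew of real
    survey effort; species membership per stream uses per-species
    inclusion probabilities plus lognormal abundance weights so species
    sample sizes span orders of magnitude. The same seed reproduces the
    dataset exactly.
    """
    labels = config.labels()
    X = generate_predictor_matrix(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    gamma = config.sigma_agency * rng.standard_normal(config.n_agencies)
    phi = config.sigma_region * rng.standard_normal(config.n_ecoregions)
    eta = config.sigma_species * rng.standard_normal(config.n_species)
    beta = config.beta_full

    stream_agency = rng.integers(0, config.n_agencies, size=config.n_streams)
    stream_region = rng.integers(0, config.n_ecoregions, size=config.n_streams)

    mu = config.fish_per_stream_mean
    size = config.fish_per_stream_size
    counts = rng.negative_binomial(size, size / (size + mu), size=config.n_streams)
    counts = np.maximum(counts, 1)

    weights = rng.lognormal(0.0, config.species_abundance_sd, size=config.n_species)
    incl = rng.beta(*config.species_inclusion, size=config.n_species)
    present = rng.random((config.n_streams, config.n_species)) < incl[None, :]
    empty = ~present.any(axis=1)
    present[empty, int(np.argmax(weights))] = True

    stream_lp = config.beta0 + X.to_numpy() @ beta

    stream_idx = np.repeat(np.arange(config.n_streams), counts)
    n = stream_idx.size
    # species draw per fish, restricted to the stream's community
    w_matrix = present * weights[None, :]
    w_matrix = w_matrix / w_matrix.sum(axis=1, keepdims=True)
    cum = np.cumsum(w_matrix, axis=1)
    u = rng.random(n)
    species_idx = np.minimum((u[:, None] > cum[stream_idx]).sum(axis=1), config.n_species - 1)

    agency_idx = stream_agency[stream_idx]
    region_idx = stream_region[stream_idx]
    lp = stream_lp[stream_idx] + gamma[agency_idx] + phi[region_idx] + eta[species_idx]
    y = (rng.random(n) < inverse_logit(lp)).astype(int)
    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)

    obs = pd.DataFrame(
        {
            "stream_id": np.asarray(labels["stream"])[stream_idx],
            "species": np.asarray(labels["species"])[species_idx],
            "agency": np.asarray(labels["agency"])[agency_idx],
            "ecoregion": np.asarray(labels["ecoregion"])[region_idx],
            "year": years,
            "delt": y,
        }
    )
    truth = GroundTruth(
        beta0=config.beta0,
        beta=pd.Series(beta, index=labels["predictor"]),
        gamma=pd.Series(gamma, index=labels["agency"]),
        phi=pd.Series(phi, index=labels["ecoregion"]),
        eta=pd.Series(eta, index=labels["species"]),
        sigma_agency=config.sigma_agency,
        sigma_region=config.sigma_region,
        sigma_species=config.sigma_species,
        stream_lp=pd.Series(stream_lp, index=labels["stream"]),
        config=config,
    )
    return obs, X, truth


def marginal_prevalence(beta0: float, total_sd: float, n_nodes: int = 81) -> float:
    """E[logit^-1(beta0 + e)], e ~ N(0, total_sd^2), by Gauss-Hermite."""
    if total_sd == 0.0:
        return inverse_logit(beta0)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    vals = inverse_logit(beta0 + total_sd * nodes)
    return float(np.sum(weights * vals) / np.sqrt(2.0 * np.pi))


def solve_intercept(target_prevalence: float, total_sd: float) -> float:
    """Intercept whose marginal prevalence equals the target given the
    combined SD of random effects and the predictor contribution."""
    from scipy.optimize import brentq

    if not 0.0 < target_prevalence < 1.0:
        raise ConfigError("target prevalence must be in (0, 1)")
    f = lambda b0: marginal_prevalence(b0, total_sd) - target_prevalence
    return float(brentq(f, -30.0, 30.0))


def study_mimic_config(
    scale: float = 20.0,
    target_prevalence: float = 0.014,
    seed: int = 0,
    collinear_pair: bool = False,
) -> GeneratorConfig:
    """A canned configuration at the structure of the regional study.

    57 species, 7 agencies, 9 ecoregions, 1,196 streams and 46 predictors,
    with 5 nonzero coefficients (two negative) standing in for the
    strongest landscape effects, agency/species/ecoregion random-effect
    SDs of 1.5 / 1.2 / 0.3 on the logit scale (agencies and species spread
    occurrence over roughly two orders of magnitude, ecoregions are
    tight), and an intercept solved so the marginal prevalence matches the
    target. ``scale`` divides the mean fish count per stream (full scale:
    149); the default 20x reduction keeps integration runs desk-sized.
    Intended for structure-faithful testing, not fidelity claims.
    """
    sigma_a, sigma_s, sigma_r = 1.5, 1.2, 0.3
    beta = (0.8, 0.6, -0.6, 0.5, -0.5)
    total_sd = float(np.sqrt(sigma_a**2 + sigma_s**2 + sigma_r**2 + np.sum(np.square(beta))))
    beta0 = solve_intercept(target_prevalence, total_sd)
    return GeneratorConfig(
        n_species=57,
        n_agencies=7,
        n_ecoregions=9,
        n_streams=1196,
        n_predictors=46,
        fish_per_stream_mean=149.0 / scale,
        fish_per_stream_size=1.0,
        beta0=beta0,
        beta=beta,
        sigma_agency=sigma_a,
        sigma_region=sigma_r,
        sigma_species=sigma_s,
        predictor_correlation="collinear_pair" if collinear_pair else "independent",
        species_abundance_sd=1.5,
        seed=seed,
    )
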