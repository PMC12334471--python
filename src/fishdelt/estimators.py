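"""scikit-learn style estimator for the occurrence models.

:class:`DeltOccurrenceModel` wraps spec construction, NUTS sampling and
posterior summarization behind ``fit`` / ``predict_proba``, so the model
composes with sklearn tooling (``get_params``/``set_params``, ``clone``,
pipelines feeding a screened and standardized design matrix).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ShapeError
from .inference import PosteriorDraws, SamplerConfig, check_convergence, sample_posterior
from .model import ModelData, ModelSpec, build_spec, inverse_logit
from .summaries import effect_table, group_probability_table, prediction_curve


def _encode(labels, name: str) -> tuple[np.ndarray, tuple[str, ...]]:
    arr = pd.Series(labels, dtype=str).str.strip()
    if (arr == "").any():
        raise ValueError(f"empty {name} label")
    levels = tuple(sorted(arr.unique()))
    lookup = {lab: i for i, lab in enumerate(levels)}
    return arr.map(lookup).to_numpy(dtype=np.int64), levels


def make_model_data(
    y,
    X=None,
    *,
    agency=None,
    ecoregion=None,
    species=None,
    stream=None,
) -> tuple[ModelData, dict[str, tuple[str, ...]]]:
    """Assemble observation-aligned arrays into a :class:`ModelData`.

    ``X`` may be an (n, P) design (one row per observation) or a
    stream-indexed DataFrame combined with per-observation ``stream``
    labels; factor arguments are per-observation label arrays. Returns the
    data plus the encoded factor level tuples.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    levels: dict[str, tuple[str, ...]] = {}
    idx = {}
    for name, arr in (("agency", agency), ("ecoregion", ecoregion), ("species", species)):
        if arr is not None:
            enc, lev = _encode(arr, name)
            if enc.shape[0] != n:
                raise ShapeError(f"{name} labels must align with y")
            idx[name] = enc
            levels[name] = lev
        else:
            idx[name] = None
            levels[name] = ()

    if X is None:
        X_stream = np.zeros((1, 0))
        stream_idx = np.zeros(n, dtype=np.int64)
        stream_ids: tuple[str, ...] = ()
    elif stream is not None:
        if not isinstance(X, pd.DataFrame):
            raise ShapeError("per-stream X must be a stream-indexed DataFrame")
        stream_labels = pd.Series(stream, dtype=str).str.strip()
        missing = sorted(set(stream_labels) - set(X.index.astype(str)))
        if missing:
            raise ShapeError(f"streams missing from the predictor table: {missing[:5]}")
        stream_ids = tuple(X.index.astype(str))
        lookup = {s: i for i, s in enumerate(stream_ids)}
        stream_idx = stream_labels.map(lookup).to_numpy(dtype=np.int64)
        X_stream = X.to_numpy(dtype=float)
    else:
        X_arr = np.atleast_2d(np.asarray(X, dtype=float))
        if X_arr.shape[0] != n:
            raise ShapeError("X rows must align with y (or pass stream labels)")
        X_stream = X_arr
        stream_idx = np.arange(n, dtype=np.int64)
        stream_ids = ()

    data = ModelData(
        y=y,
        stream_idx=stream_idx,
        X_stream=X_stream,
        agency_idx=idx["agency"],
        region_idx=idx["ecoregion"],
        species_idx=idx["species"],
        stream_ids=stream_ids,
    )
    return data, levels


class DeltOccurrenceModel(BaseEstimator):
    """Bayesian hierarchical logistic occurrence model with NUTS inference.

    Parameters mirror the model and sampler knobs: the variant, the
    fixed-effect prior (regularized horseshoe by default when predictors
    are present, with expected nonzero count ``p0``, slab scale/df and an
    optional explicit global scale), the half-Cauchy scale of the
    random-effect SDs, and the sampler settings. ``random_state`` seeds
    every chain deterministically.

    Fitted attributes: ``spec_`` (resolved model spec), ``draws_``
    (:class:`PosteriorDraws`), ``convergence_`` (numeric report) and
    ``coef_table_`` (per-predictor posterior summaries) when predictors
    are present.
    """

    def __init__(
        self,
        variant: str = "conditional",
        beta_prior: str = "horseshoe",
        p0: float = 5.0,
        slab_scale: float = 2.0,
        slab_df: float = 4.0,
        global_scale: float | None = None,
        beta_scale: float = 5.0,
        intercept_scale: float = 5.0,
        sigma_scale: float = 2.5,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        target_accept: float = 0.95,
        max_treedepth: int = 10,
        parameterization: str = "non_centered",
        random_state: int = 0,
    ):
        self.variant = variant
        self.beta_prior = beta_prior
        self.p0 = p0
        self.slab_scale = slab_scale
        self.slab_df = slab_df
        self.global_scale = global_scale
        self.beta_scale = beta_scale
        self.intercept_scale = intercept_scale
        self.sigma_scale = sigma_scale
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.parameterization = parameterization
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, *, agency=None, ecoregion=None, species=None, stream=None,
            predictor_names=None):
        """Sample the posterior for observations ``y``.

        ``X`` is the standardized design matrix (or stream-indexed table
        plus per-observation ``stream`` labels), ``None`` for the
        unconditional variant. Factor labels are per-observation arrays;
        the species-specific variant requires single-species data.
        """
        data, levels = make_model_data(
            y, X, agency=agency, ecoregion=ecoregion, species=species, stream=stream
        )
        if predictor_names is None:
            if isinstance(X, pd.DataFrame):
                predictor_names = tuple(str(c) for c in X.columns)
            else:
                predictor_names = tuple(f"x{j}" for j in range(data.n_predictors))
        hyper = dict(
            beta_prior=self.beta_prior,
            p0=self.p0,
            slab_scale=self.slab_scale,
            slab_df=self.slab_df,
            global_scale=self.global_scale,
            beta_scale=self.beta_scale,
            intercept_scale=self.intercept_scale,
            sigma_scale=self.sigma_scale,
        )
        if levels["agency"] and levels["ecoregion"]:
            self.spec_ = build_spec(
                self.variant,
                agencies=levels["agency"],
                ecoregions=levels["ecoregion"],
                species=levels["species"],
                predictors=tuple(predictor_names),
                **hyper,
            )
        else:
            # no-random-effect reduction: the bare logit-linear model
            self.spec_ = ModelSpec(
                variant=self.variant if self.variant != "species_specific" else "conditional",
                agencies=levels["agency"],
                ecoregions=levels["ecoregion"],
                species=levels["species"],
                predictors=tuple(predictor_names) if self.variant != "unconditional" else (),
                **hyper,
            )
        config = SamplerConfig(
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.random_state,
            target_accept=self.target_accept,
            parameterization=self.parameterization,
            max_treedepth=self.max_treedepth,
        )
        self.data_ = data
        self.draws_ = sample_posterior(self.spec_, data, config)
        self.convergence_ = check_convergence(self.draws_)
        if self.spec_.n_predictors:
            self.coef_table_ = effect_table(self.draws_)
        self.classes_ = np.array([0, 1])
        return self

    # ------------------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted yet; call fit first")

    def predict_proba(self, X=None, *, agency=None, ecoregion=None, species=None):
        """Posterior-mean occurrence probability per row.

        Factor labels unseen in fitting (or omitted) contribute their
        prior mean of zero. Returns an (n, 2) array of [P(y=0), P(y=1)].
        """
        self._check_fitted()
        draws = self.draws_
        b0 = draws.stacked("beta0")
        if self.spec_.n_predictors:
            if X is None:
                raise ValueError("this model was fitted with predictors; pass X")
            X_arr = np.atleast_2d(np.asarray(
                X[list(self.spec_.predictors)] if isinstance(X, pd.DataFrame) else X, dtype=float
            ))
            n = X_arr.shape[0]
            lp = b0[None, :] + X_arr @ draws.stacked("beta").T
        else:
            n = len(agency) if agency is not None else (
                len(species) if species is not None else len(ecoregion))
            lp = np.tile(b0, (n, 1))
        for labels, coord, block in (
            (agency, "agency", "gamma"), (ecoregion, "ecoregion", "phi"), (species, "species", "eta")
        ):
            if labels is not None and block in draws.params:
                levels = list(draws.coords[coord])
                eff = draws.stacked(block)
                lookup = {lab: i for i, lab in enumerate(levels)}
                for row, lab in enumerate(pd.Series(labels, dtype=str).str.strip()):
                    if lab in lookup:
                        lp[row] += eff[:, lookup[lab]]
        p1 = inverse_logit(lp).mean(axis=1)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X=None, **factors):
        return (self.predict_proba(X, **factors)[:, 1] >= 0.5).astype(int)

    # ------------------------------------------------------------------
    def effect_summary(self) -> pd.DataFrame:
        """Per-predictor posterior mean, 90% CI, pd and class."""
        self._check_fitted()
        return effect_table(self.draws_)

    def group_probabilities(self, factor: str) -> pd.DataFrame:
        self._check_fitted()
        return group_probability_table(self.draws_, factor)

    def response_curve(self, predictor: str, grid, transform=None):
        self._check_fitted()
        return prediction_curve(self.draws_, predictor, grid, transform=transform)
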