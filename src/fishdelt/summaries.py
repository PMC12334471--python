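"""Posterior decision summaries.

Draws are turned into the quantities an analyst reports: posterior means
with 90% equal-tailed credible intervals, the probability of direction
(pd — the posterior probability that an effect shares the sign of its
posterior mean), a three-way significance classification, occurrence
probabilities per species/agency/ecoregion, and single-predictor response
curves on the probability scale.

Classification rule: an effect is ``significant`` when its 90% interval
excludes zero; otherwise ``pd_significant`` (potentially biologically
meaningful) when pd exceeds 0.90 strictly; otherwise ``not_significant``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorDraws
from .model import inverse_logit

CLASSES = ("significant", "pd_significant", "not_significant")


def equal_tailed_interval(draws, level: float = 0.90) -> tuple[float, float]:
    """Equal-tailed credible interval from empirical quantiles.

    Uses linear interpolation of order statistics (the default quantile
    rule), documented because endpoint values at a few thousand draws
    depend on the rule. Requires at least 2 finite draws.
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least 2 draws")
    if not np.all(np.isfinite(arr)):
        raise ValueError("draws must be finite")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(arr, [a, 1.0 - a], method="linear")
    return float(lo), float(hi)


def probability_of_direction(draws) -> float:
    """Fraction of draws sharing the sign of the posterior mean.

    Draws exactly at zero count half (the sign-symmetric continuous
    limit); if the mean itself is exactly zero the direction is undefined
    and pd is 0.5. Always in [0.5, 1] up to sampling noise of the mean's
    sign.
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError("need at least 2 draws")
    if not np.all(np.isfinite(arr)):
        raise ValueError("draws must be finite")
    mean = arr.mean()
    if mean == 0.0:
        return 0.5
    sign = 1.0 if mean > 0 else -1.0
    share = np.sum(np.sign(arr) == sign) + 0.5 * np.sum(arr == 0.0)
    return float(share / arr.size)


def classify_effect(mean: float, interval: tuple[float, float], pd_value: float) -> str:
    """Three-way significance class from interval and pd (strict pd > 0.90)."""
    lo, hi = interval
    if lo > hi:
        raise ValueError("interval lower bound exceeds upper bound")
    if not (lo <= 0.0 <= hi):
        return "significant"
    if pd_value > 0.90:
        return "pd_significant"
    return "not_significant"


@dataclass(frozen=True)
class EffectSummary:
    """Posterior mean, 90% interval, pd and class for one parameter."""

    name: str
    mean: float
    lower: float
    upper: float
    pd: float
    cls: str


def summarize_draws(name: str, draws, level: float = 0.90) -> EffectSummary:
    arr = np.asarray(draws, dtype=float).ravel()
    lo, hi = equal_tailed_interval(arr, level)
    pd_value = probability_of_direction(arr)
    mean = float(arr.mean())
    return EffectSummary(name, mean, lo, hi, pd_value, classify_effect(mean, (lo, hi), pd_value))


def effect_table(draws: PosteriorDraws, block: str = "beta", level: float = 0.90) -> pd.DataFrame:
    """One EffectSummary row per element of a draw block (default: the
    landscape coefficients)."""
    arr = draws.stacked(block)
    if arr.ndim == 1:
        arr = arr[:, None]
        names = [block]
    else:
        key = {"beta": "predictor", "lam": "predictor", "gamma": "agency",
               "phi": "ecoregion", "eta": "species"}[block]
        names = list(draws.coords[key])
    rows = [summarize_draws(n, arr[:, j], level).__dict__ for j, n in enumerate(names)]
    return pd.DataFrame(rows)


_FACTOR_BLOCK = {"species": "eta", "agency": "gamma", "ecoregion": "phi"}


def group_probability_table(
    draws: PosteriorDraws, factor: str, level: float = 0.90
) -> pd.DataFrame:
    """Per-level occurrence probabilities for one random-effect factor.

    For each level l the draws of ``logit^-1(beta0 + effect_l)`` are
    summarized, conditioning on the other random effects at their prior
    mean of zero; a ``population_average`` row summarizes
    ``logit^-1(beta0)``. Columns ``effect_*`` carry the summary of the
    level's logit-scale effect itself, whose interval-vs-zero reading is
    how levels are flagged as above or below the average.
    """
    if factor not in _FACTOR_BLOCK:
        raise ValueError(f"factor must be one of {sorted(_FACTOR_BLOCK)}, got {factor!r}")
    block = _FACTOR_BLOCK[factor]
    if block not in draws.params:
        raise ValueError(f"the fitted model has no {factor} random effect")
    b0 = draws.stacked("beta0")
    eff = draws.stacked(block)
    labels = list(draws.coords[factor])
    rows = []
    pop = summarize_draws("population_average", inverse_logit(b0), level)
    rows.append({**pop.__dict__, "effect_mean": 0.0, "effect_lower": 0.0,
                 "effect_upper": 0.0, "effect_pd": 0.5, "effect_cls": "not_significant"})
    for j, lab in enumerate(labels):
        prob = summarize_draws(lab, inverse_logit(b0 + eff[:, j]), level)
        es = summarize_draws(lab, eff[:, j], level)
        rows.append({**prob.__dict__, "effect_mean": es.mean, "effect_lower": es.lower,
                     "effect_upper": es.upper, "effect_pd": es.pd, "effect_cls": es.cls})
    return pd.DataFrame(rows)


@dataclass
class ResponseCurve:
    """Posterior mean and credible band of Pr(DELT) along one predictor.

    The grid is in the predictor's original units; all other predictors
    sit at their study-average (0 on the standardized scale) and random
    effects at 0.
    """

    predictor: str
    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.90

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictor,
                "value": self.grid,
                "mean": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def prediction_curve(
    draws: PosteriorDraws,
    predictor: str,
    grid,
    transform=None,
    level: float = 0.90,
) -> ResponseCurve:
    """Single-predictor response curve on the probability scale.

    ``transform`` is the fitted standardizer (the transform record) used
    to map the original-unit grid onto the standardized scale the model
    was fitted on; pass ``None`` if the grid is already standardized.
    """
    if "beta" not in draws.params:
        raise ValueError("prediction curves require a model with predictors")
    names = list(draws.coords["predictor"])
    if predictor not in names:
        raise ValueError(f"predictor {predictor!r} was not in the fitted model")
    j = names.index(predictor)
    grid = np.asarray(grid, dtype=float)
    z = transform.transform_column(predictor, grid) if transform is not None else grid
    b0 = draws.stacked("beta0")
    bf = draws.stacked("beta")[:, j]
    mean = np.empty_like(grid, dtype=float)
    lower = np.empty_like(mean)
    upper = np.empty_like(mean)
    for i, zi in enumerate(z):
        p = inverse_logit(b0 + bf * zi)
        mean[i] = p.mean()
        lower[i], upper[i] = equal_tailed_interval(p, level)
    return ResponseCurve(predictor, grid, mean, lower, upper, level)
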