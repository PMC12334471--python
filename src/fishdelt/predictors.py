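"""Stream-level landscape predictor preparation.

The predictor table has one row per stream reach and one column per
upstream-watershed landscape attribute (land use, climate, geology, BMP
implementation, ...). Before model fitting the table goes through three
steps: multi-year attributes are collapsed to a single per-stream mean of
the annual values, collinear predictors are screened out with a Spearman
rank-correlation rule, and the surviving columns are standardized to mean
0 / SD 1 (sample SD) so that coefficients are comparable and the sparsity
prior acts on a common scale.

Both reusable steps are scikit-learn transformers
(:class:`PredictorStandardizer`, :class:`SpearmanCollinearityFilter`) so
they compose with pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegeneratePredictorError, MissingDataError


def validate_predictor_table(table: pd.DataFrame) -> None:
    """Check the stream x predictor contract.

    The index (stream id) must be unique and every column must have at
    least two distinct finite values — a constant column cannot be
    standardized and carries no information.
    """
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated stream ids: {dupes[:5]}")
    for name in table.columns:
        vals = table[name].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if np.unique(finite).size < 2:
            raise DegeneratePredictorError(f"predictor {name!r} has < 2 distinct finite values")


def aggregate_annual_means(per_year_values) -> pd.Series:
    """Collapse per-year predictor values to one mean value per stream.

    Accepts either a mapping ``{stream: {year: value}}`` or a long
    DataFrame with columns ``stream_id``, ``year``, ``value``. The result
    is the unweighted arithmetic mean of the available annual values, the
    convention used when a multi-year attribute is paired with a static
    per-stream record.
    """
    if isinstance(per_year_values, pd.DataFrame):
        frame = per_year_values
        items = {sid: grp["value"].to_numpy(dtype=float) for sid, grp in frame.groupby("stream_id")}
    else:
        items = {sid: np.asarray(list(yv.values()), dtype=float) for sid, yv in per_year_values.items()}
    out = {}
    for sid, vals in items.items():
        if vals.size == 0 or not np.all(np.isfinite(vals)):
            raise MissingDataError(f"stream {sid!r} has no usable yearly values")
        out[sid] = float(vals.mean())
    if not out:
        raise MissingDataError("no streams with yearly values")
    return pd.Series(out, name="value").rename_axis("stream_id")


class PredictorStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise (x - mean) / sd scaling with the sample SD (ddof=1).

    The fitted ``mean_`` / ``scale_`` pair is the transform record used to
    map new data and prediction grids onto the standardized scale and to
    invert curves back to original units.
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        vals = X.to_numpy(dtype=float)
        sd = vals.std(axis=0, ddof=1)
        for j, s in enumerate(sd):
            if not np.isfinite(s) or s == 0.0:
                raise DegeneratePredictorError(
                    f"predictor {X.columns[j]!r} is constant; cannot standardize"
                )
        self.mean_ = vals.mean(axis=0)
        self.scale_ = sd
        self.n_features_in_ = vals.shape[1]
        return self

    def transform(self, X):
        X = self._as_frame(X, like=self.feature_names_in_)
        vals = (X.to_numpy(dtype=float) - self.mean_) / self.scale_
        return pd.DataFrame(vals, index=X.index, columns=X.columns)

    def inverse_transform(self, X):
        X = self._as_frame(X, like=self.feature_names_in_)
        vals = X.to_numpy(dtype=float) * self.scale_ + self.mean_
        return pd.DataFrame(vals, index=X.index, columns=X.columns)

    def transform_column(self, name: str, values) -> np.ndarray:
        """Standardize raw values of a single named predictor."""
        j = int(np.flatnonzero(self.feature_names_in_ == name)[0])
        return (np.asarray(values, dtype=float) - self.mean_[j]) / self.scale_[j]

    @staticmethod
    def _as_frame(X, like=None) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        cols = like if like is not None else [f"x{j}" for j in range(np.asarray(X).shape[1])]
        return pd.DataFrame(np.asarray(X, dtype=float), columns=list(cols))


def standardize_predictors(table: pd.DataFrame) -> tuple[pd.DataFrame, PredictorStandardizer]:
    """Standardize every column; returns the scaled table and the transform record."""
    scaler = PredictorStandardizer().fit(table)
    return scaler.transform(table), scaler


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average ranks. Requires two equal-length vectors of at
    least 3 finite values, neither constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector has undefined rank correlation")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


class SpearmanCollinearityFilter(TransformerMixin, BaseEstimator):
    """Greedy collinearity screen on Spearman rank correlation.

    Predictors are visited in ``priority`` order (default: column order).
    A predictor is dropped iff its |rho| with any already-retained
    predictor reaches ``threshold``; each drop is logged with the partner
    and the offending correlation. After fitting, no retained pair has
    |rho| >= threshold.

    Parameters
    ----------
    threshold : float in (0, 1], default 0.90
        Retention rule is |rho| < threshold.
    priority : sequence of column names or None
        Visit order; must be a permutation of the columns. Earlier names
        win ties, which makes the screen deterministic and auditable.
    use_abs : bool, default True
        Screen on |rho| rather than signed rho.
    """

    def __init__(self, threshold: float = 0.90, priority: Sequence[str] | None = None,
                 use_abs: bool = True):
        self.threshold = threshold
        self.priority = priority
        self.use_abs = use_abs

    def fit(self, X, y=None):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        X = PredictorStandardizer._as_frame(X)
        cols = list(X.columns)
        order = list(self.priority) if self.priority is not None else cols
        if sorted(order) != sorted(cols):
            raise ValueError("priority must be a permutation of the predictor columns")
        corr = self._corr_matrix(X)
        retained: list[str] = []
        dropped: list[dict] = []
        idx = {c: i for i, c in enumerate(cols)}
        for name in order:
            hit = None
            for kept in retained:
                rho = corr[idx[name], idx[kept]]
                val = abs(rho) if self.use_abs else rho
                if val >= self.threshold:
                    hit = (kept, rho)
                    break
            if hit is None:
                retained.append(name)
            else:
                dropped.append({"dropped": name, "partner": hit[0], "rho": float(hit[1])})
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        self.retained_ = [c for c in cols if c in set(retained)]
        self.dropped_ = dropped
        self.report_ = pd.DataFrame(dropped, columns=["dropped", "partner", "rho"])
        return self

    def transform(self, X):
        X = PredictorStandardizer._as_frame(X, like=self.feature_names_in_)
        return X.loc[:, self.retained_]

    @staticmethod
    def _corr_matrix(X: pd.DataFrame) -> np.ndarray:
        vals = X.to_numpy(dtype=float)
        if vals.shape[1] == 1:
            return np.ones((1, 1))
        res = stats.spearmanr(vals)
        corr = np.atleast_2d(res.statistic)
        if corr.shape != (vals.shape[1], vals.shape[1]):  # spearmanr collapses 2 columns
            r = float(corr.ravel()[0]) if corr.size else float(res.statistic)
            corr = np.array([[1.0, r], [r, 1.0]])
        return corr


def drop_collinear(
    table: pd.DataFrame,
    threshold: float = 0.90,
    priority: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen a predictor table; returns (reduced table, drop report)."""
    screen = SpearmanCollinearityFilter(threshold=threshold, priority=priority).fit(table)
    return screen.transform(table), screen.report_
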