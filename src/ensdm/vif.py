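"""Multicollinearity screening via variance inflation factors.

The VIF of predictor *i* is ``1 / (1 - R_i^2)`` where ``R_i^2`` comes from
an ordinary least squares regression of that predictor on all the others
(with intercept).  Pruning removes the current worst offender — the
predictor with the largest VIF at or above the threshold — one at a time
until every remaining VIF is below the threshold (default 10, the standard
retention rule for suitability modelling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DegenerateDataError, ValidationError

_INF_R2 = 1.0 - 1e-12


def _as_frame(X, columns=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if columns is None:
        columns = [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(columns))


def compute_vif(X, target_column) -> float:
    """VIF of one column of a design matrix against all the others.

    Returns ``inf`` when the column is an exact linear combination of the
    rest (R^2 = 1); raises :class:`DegenerateDataError` for a constant
    target column.
    """
    df = _as_frame(X)
    if target_column not in df.columns:
        raise ValidationError(f"target column {target_column!r} not in matrix")
    if len(df) < 3 or df.shape[1] < 2:
        raise ValidationError("need at least 3 rows and 2 columns")
    y = df[target_column].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError(f"column {target_column!r} is constant")
    others = df.drop(columns=[target_column]).to_numpy(dtype=float)
    A = np.column_stack([np.ones(len(df)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= _INF_R2:
        return float("inf")
    return 1.0 / (1.0 - r2)


@dataclass
class VifTable:
    """Result of iterative VIF pruning."""

    entries: list[tuple[str, float]]          # final VIFs of retained columns
    retained: list[str]
    dropped: list[tuple[str, float]] = field(default_factory=list)  # (name, VIF at removal)
    threshold: float = 10.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": n, "vif": v, "status": "retained"} for n, v in self.entries
        ] + [
            {"variable": n, "vif": v, "status": "dropped"} for n, v in self.dropped
        ]
        return pd.DataFrame(rows)


def prune_by_vif(X, threshold: float = 10.0) -> VifTable:
    """Greedy stepwise VIF pruning.

    At each step the column with the largest VIF >= threshold is removed
    (ties broken towards the column later in input order) and all VIFs are
    recomputed; iteration stops when every remaining VIF is below the
    threshold.  If fewer than 2 columns remain mid-iteration the survivors
    are retained with a warning.
    """
    df = _as_frame(X)
    if df.shape[1] < 2:
        raise ValidationError("need at least 2 columns to prune")
    remaining = list(df.columns)
    dropped: list[tuple[str, float]] = []
    while True:
        if len(remaining) < 2:
            warnings.warn(
                "fewer than 2 columns remain; VIF undefined, retaining survivors",
                stacklevel=2,
            )
            entries = [(n, float("nan")) for n in remaining]
            return VifTable(entries, remaining, dropped, threshold)
        vifs = {name: compute_vif(df[remaining], name) for name in remaining}
        worst_vif = max(vifs.values())
        if worst_vif < threshold:
            entries = [(n, vifs[n]) for n in remaining]
            return VifTable(entries, remaining, dropped, threshold)
        # ties -> drop the offender later in input order
        worst = [n for n, v in vifs.items() if v == worst_vif][-1]
        dropped.append((worst, worst_vif))
        remaining.remove(worst)


class VIFPruner(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer wrapping :func:`prune_by_vif`.

    Parameters
    ----------
    threshold : float, default 10.0
        Columns are removed until every remaining VIF is below this value.

    Attributes
    ----------
    table_ : VifTable
        Full pruning record (final VIFs, removal order).
    retained_ : list of str
        Names of the surviving columns.
    support_ : ndarray of bool
        Boolean mask over the input columns.
    """

    def __init__(self, threshold: float = 10.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        df = _as_frame(X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        self.table_ = prune_by_vif(df, threshold=self.threshold)
        self.retained_ = list(self.table_.retained)
        self.support_ = np.array([c in self.retained_ for c in df.columns])
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        if isinstance(X, pd.DataFrame):
            return X[self.retained_]
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "retained_")
        return np.asarray(self.retained_, dtype=object)
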