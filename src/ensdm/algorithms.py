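"""Presence-only and presence/background suitability algorithms.

Four canonical species-distribution learners are implemented from scratch
behind one scikit-learn-style contract:

``fit(X, y=None)``
    ``y`` uses 1 = presence, 0 = background.  Presence-only algorithms
    (:class:`BioclimEnvelope`, :class:`DomainSimilarity`,
    :class:`MahalanobisNiche`) train on the presence rows alone and simply
    ignore background rows; :class:`LogisticSDM` needs both classes.
``score_samples(X) -> ndarray in [0, 1]``
    Deterministic per-row suitability score.

A registry maps short algorithm ids to classes so ensembles can be
assembled from configuration, and :class:`SklearnSDM` adapts any external
probabilistic classifier (random forest, SVM, gradient boosting, ...) to
the same contract.

Score scales
------------
Each algorithm family ranks candidate sites; mapping those ranks onto
[0, 1] is a modelling choice, made here as follows:

* BIOCLIM: per-variable midrank percentile ``p`` of the candidate within
  the presence sample, folded to ``2 * min(p, 1 - p)`` (1 at the presence
  median, 0 outside the envelope); overall score is the minimum over
  variables (Liebig-style limiting factor).
* DOMAIN: Gower similarity to the **nearest** presence point, clipped to
  [0, 1]; per-variable distances are normalized by the presence range.
* Mahalanobis: squared distance to the presence centroid under the
  presence covariance, mapped through the chi-square survival function
  with m degrees of freedom (1 at the centroid, decreasing in distance).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator, clone
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, DegenerateDataError, NamingError, ValidationError
from .geodata import ClimateStack, GridSpec

REGISTRY: dict[str, type] = {}


def register(algorithm_id: str):
    """Class decorator adding an SDM class to the registry."""

    def deco(cls):
        REGISTRY[algorithm_id] = cls
        cls.algorithm_id = algorithm_id
        return cls

    return deco


def make_sdm(algorithm_id: str, **params) -> "BaseSDM":
    if algorithm_id not in REGISTRY:
        raise ValidationError(
            f"unknown algorithm {algorithm_id!r}; registered: {sorted(REGISTRY)}"
        )
    return REGISTRY[algorithm_id](**params)


def _to_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


class BaseSDM(BaseEstimator):
    """Common fit/score plumbing for all suitability learners."""

    algorithm_id = "base"
    requires_background = False

    def _presence_rows(self, X, y):
        M, names = _to_matrix(X)
        if M.ndim != 2:
            raise ValidationError("X must be 2-D")
        if y is not None:
            y = np.asarray(y)
            M = M[y == 1]
        return M, names

    def fit(self, X, y=None):
        M, names = self._presence_rows(X, y)
        self.variable_names_ = names
        self.n_features_in_ = M.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self._fit_presence(M, X, y)
        return self

    def _fit_presence(self, presences, X, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def _score(self, M: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def score_samples(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        M, names = _to_matrix(X)
        if names is not None and self.variable_names_ is not None:
            missing = [n for n in self.variable_names_ if n not in names]
            if missing:
                raise NamingError(f"missing variables: {missing}")
            M = np.asarray(X[self.variable_names_], dtype=float)
        if M.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {M.shape[1]} columns, model expects {self.n_features_in_}"
            )
        scores = self._score(M)
        return np.clip(scores, 0.0, 1.0)

    # serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "n_features_in_")
        return {
            "algorithm_id": self.algorithm_id,
            "variable_names": self.variable_names_,
            "params": self.get_params(),
            "state": self._state_dict(),
        }

    def _state_dict(self) -> dict:  # pragma: no cover - abstract
        raise NotImplementedError

    def _load_state(self, state: dict) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


def save_sdm(model: BaseSDM, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2)


def load_sdm(source) -> BaseSDM:
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = json.load(fh)
    model = make_sdm(doc["algorithm_id"], **doc.get("params", {}))
    model.variable_names_ = doc["variable_names"]
    model.n_features_in_ = len(doc["variable_names"]) if doc["variable_names"] else None
    model._load_state(doc["state"])
    if model.n_features_in_ is None:
        model.n_features_in_ = model._n_features_from_state()
    return model


@register("bioclim")
class BioclimEnvelope(BaseSDM):
    """Climate-envelope (BIOCLIM-style) suitability model.

    For each variable the candidate value's midrank percentile within the
    presence sample, ``p = (n_below + 0.5 * n_equal) / n``, is folded into
    a symmetric score ``2 * min(p, 1 - p)``; the overall suitability is the
    minimum over variables.
    """

    requires_background = False
    min_presences = 5

    def _fit_presence(self, presences, X, y):
        if presences.shape[0] < self.min_presences:
            raise DataError(
                f"bioclim needs >= {self.min_presences} presence rows"
            )
        self.sorted_values_ = [np.sort(presences[:, j]) for j in range(presences.shape[1])]
        self.n_presences_ = presences.shape[0]

    def _score(self, M):
        n = self.n_presences_
        score = np.ones(M.shape[0])
        for j, vals in enumerate(self.sorted_values_):
            below = np.searchsorted(vals, M[:, j], side="left")
            upto = np.searchsorted(vals, M[:, j], side="right")
            p = (below + 0.5 * (upto - below)) / n
            score = np.minimum(score, 2.0 * np.minimum(p, 1.0 - p))
        return score

    def _state_dict(self):
        return {"sorted_values": [v.tolist() for v in self.sorted_values_]}

    def _load_state(self, state):
        self.sorted_values_ = [np.asarray(v, dtype=float) for v in state["sorted_values"]]
        self.n_presences_ = len(self.sorted_values_[0])

    def _n_features_from_state(self):
        return len(self.sorted_values_)


@register("domain")
class DomainSimilarity(BaseSDM):
    """DOMAIN-style nearest-neighbour Gower similarity model.

    The candidate's score is its similarity ``1 - d`` to the closest
    presence point, where ``d`` is the Gower distance: the mean over
    variables of ``|x_k - x_ik| / range_k`` with the range taken over the
    presence sample.  A zero-range variable contributes distance 0 on exact
    match and 1 otherwise.  Scores are clipped to [0, 1].
    """

    requires_background = False
    min_presences = 2
    _chunk = 4096

    def _fit_presence(self, presences, X, y):
        if presences.shape[0] < self.min_presences:
            raise DataError(f"domain needs >= {self.min_presences} presence rows")
        self.presences_ = presences.copy()
        self.ranges_ = np.ptp(presences, axis=0)

    def _score(self, M):
        P = self.presences_
        r = self.ranges_
        safe_r = np.where(r > 0, r, 1.0)
        out = np.empty(M.shape[0])
        for start in range(0, M.shape[0], self._chunk):
            block = M[start : start + self._chunk]
            diff = np.abs(block[:, None, :] - P[None, :, :])  # (b, P, m)
            contrib = diff / safe_r
            if np.any(r == 0):
                zero = r == 0
                contrib[:, :, zero] = (diff[:, :, zero] != 0).astype(float)
            d = contrib.mean(axis=2).min(axis=1)
            out[start : start + self._chunk] = 1.0 - d
        return out

    def _state_dict(self):
        return {"presences": self.presences_.tolist()}

    def _load_state(self, state):
        self.presences_ = np.asarray(state["presences"], dtype=float)
        self.ranges_ = np.ptp(self.presences_, axis=0)

    def _n_features_from_state(self):
        return self.presences_.shape[1]


@register("mahalanobis")
class MahalanobisNiche(BaseSDM):
    """Mahalanobis-distance niche model with a chi-square score mapping.

    Suitability of a candidate x is ``P(chi2_m > D^2)`` where
    ``D^2 = (x - mu)' Sigma^-1 (x - mu)`` uses the presence sample mean and
    covariance.  An ill-conditioned covariance is ridge-stabilized by
    ``eps * trace(Sigma) / m`` on the diagonal with eps = 1e-8.
    """

    requires_background = False
    ridge_eps = 1e-8
    _max_cond = 1e10

    def _fit_presence(self, presences, X, y):
        n, m = presences.shape
        if n < 2:
            raise DataError("mahalanobis needs >= 2 presence rows")
        if n <= m:
            warnings.warn(
                "mahalanobis: fewer presence rows than variables + 1; "
                "covariance is singular and will be regularized",
                stacklevel=2,
            )
        self.mean_ = presences.mean(axis=0)
        cov = np.cov(presences, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        tr = np.trace(cov)
        if tr <= 0:
            raise DegenerateDataError("all presence rows identical")
        if not np.all(np.isfinite(cov)) or np.linalg.cond(cov) > self._max_cond:
            cov = cov + self.ridge_eps * tr / m * np.eye(m)
        self.cov_ = cov
        self._chol = np.linalg.cholesky(self.cov_)

    def _score(self, M):
        diff = M - self.mean_
        z = np.linalg.solve(self._chol, diff.T)
        d2 = (z**2).sum(axis=0)
        return chi2.sf(d2, df=self.n_features_in_)

    def _state_dict(self):
        return {"mean": self.mean_.tolist(), "cov": self.cov_.tolist()}

    def _load_state(self, state):
        self.mean_ = np.asarray(state["mean"], dtype=float)
        self.cov_ = np.atleast_2d(np.asarray(state["cov"], dtype=float))
        self._chol = np.linalg.cholesky(self.cov_)

    def _n_features_from_state(self):
        return len(self.mean_)


@register("glm")
class LogisticSDM(BaseSDM):
    """Maximum-likelihood logistic regression on presence/background labels.

    Unpenalized fit with intercept; under perfect separation the optimizer
    stops at the iteration cap with a convergence warning and the capped
    fit is returned.
    """

    requires_background = True

    def __init__(self, max_iter: int = 1000):
        self.max_iter = max_iter

    def fit(self, X, y):
        M, names = _to_matrix(X)
        y = np.asarray(y)
        if set(np.unique(y)) != {0, 1}:
            raise DataError("glm needs both presence (1) and background (0) rows")
        self.variable_names_ = names
        self.n_features_in_ = M.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        self._lr = LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=self.max_iter
        )
        self._lr.fit(M, y)
        self.coef_ = self._lr.coef_[0].copy()
        self.intercept_ = float(self._lr.intercept_[0])
        return self

    def _score(self, M):
        from scipy.special import expit

        eta = M @ self.coef_ + self.intercept_
        return expit(eta)

    def _state_dict(self):
        return {"coef": self.coef_.tolist(), "intercept": self.intercept_}

    def _load_state(self, state):
        self.coef_ = np.asarray(state["coef"], dtype=float)
        self.intercept_ = float(state["intercept"])

    def _n_features_from_state(self):
        return len(self.coef_)


class SklearnSDM(BaseSDM):
    """Adapter exposing any probabilistic scikit-learn classifier as an SDM.

    The wrapped estimator is fit on presence/background labels and scored
    via ``predict_proba(...)[:, 1]``.  Register fitted-at-config-time
    members with :func:`register` or pass instances straight to an
    ensemble roster.
    """

    requires_background = True

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y):
        if self.estimator is None:
            raise ValidationError("SklearnSDM needs an estimator")
        M, names = _to_matrix(X)
        y = np.asarray(y)
        if set(np.unique(y)) != {0, 1}:
            raise DataError("adapter needs both presence and background rows")
        self.variable_names_ = names
        self.n_features_in_ = M.shape[1]
        self.estimator_ = clone(self.estimator).fit(M, y)
        return self

    def _score(self, M):
        return self.estimator_.predict_proba(M)[:, 1]

    def _state_dict(self):
        raise ValidationError("SklearnSDM does not support JSON serialization")


# ---------------------------------------------------------------------------
# Raster prediction
# ---------------------------------------------------------------------------

def predict_map(model: BaseSDM, stack: ClimateStack):
    """Apply a fitted model to every valid cell of a stack.

    Returns a :class:`~ensdm.projection.SuitabilityMap`; nodata cells stay
    masked and carry no score.
    """
    from .projection import SuitabilityMap

    names = model.variable_names_
    if names is not None:
        missing = [n for n in names if n not in stack.layers]
        if missing:
            raise NamingError(f"stack is missing variables: {missing}")
        M = stack.to_matrix(names)
    else:
        M = stack.to_matrix()
    scores = model.score_samples(pd.DataFrame(M, columns=names) if names else M)
    values = np.zeros(stack.grid.shape, dtype=float)
    values[~stack.nodata_mask] = scores
    return SuitabilityMap(stack.grid, values, stack.nodata_mask.copy())
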