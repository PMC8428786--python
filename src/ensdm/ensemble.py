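"""Model evaluation, gating, AUC-proportional weighting and ensembling.

The workflow mirrors standard ensemble suitability modelling practice:

1. split the labelled occurrence data 70/30 (stratified by label);
2. evaluate each candidate algorithm by stratified 5-fold cross-validation
   on the training split, scoring each fold by AUC;
3. gate: algorithms whose mean CV AUC falls below 0.77 are excluded;
4. weight: surviving algorithms are weighted by their AUC, weights
   normalized to sum to one; members whose normalized share falls below
   5% are dropped iteratively and the rest re-normalized;
5. the ensemble suitability of a cell is the weighted average
   ``S_e = sum_i(w_i * S_i) / sum_i(w_i)`` of member scores.

AUC here is the Mann-Whitney probability that a random presence scores
above a random background point, with ties counted one half (midranks).
The gate uses the mean cross-validated AUC; the 30% holdout is reserved
for reporting so model selection and final assessment stay separate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, clone
from sklearn.model_selection import StratifiedKFold, train_test_split

from .algorithms import BaseSDM, make_sdm, predict_map
from .errors import DataError, GateError, ValidationError
from .geodata import ClimateStack, OccurrenceSet

DEFAULT_AUC_GATE = 0.77
DEFAULT_MIN_CONTRIBUTION = 0.05
DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_K_FOLDS = 5
DEFAULT_ALGORITHMS = ("bioclim", "domain", "mahalanobis", "glm")


# ---------------------------------------------------------------------------
# Splitting and AUC
# ---------------------------------------------------------------------------

def split_data(
    occ: OccurrenceSet,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Stratified train/test split of an occurrence set."""
    labels = occ.points["label"].to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise DataError("both presence and background labels are required")
    if counts.min() < 2:
        raise DataError("each class needs at least 2 points to split")
    idx = np.arange(len(occ))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return occ.subset(np.sort(train_idx)), occ.subset(np.sort(test_idx))


def split_indices(
    y: np.ndarray, train_fraction: float = DEFAULT_TRAIN_FRACTION, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split for a 0/1 label vector."""
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(train_idx), np.sort(test_idx)


def compute_auc(scores_presence, scores_background) -> float:
    """Mann-Whitney AUC with ties counted one half, via midranks."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValidationError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2
    return float(u / (sp.size * sb.size))


def auc_from_labels(y, scores) -> float:
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    return compute_auc(scores[y == 1], scores[y == 0])


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Per-algorithm evaluation record."""

    algorithm_id: str
    fold_aucs: list[float]
    mean_auc: float
    test_auc: float | None = None
    passed_auc_gate: bool | None = None


def cross_validate(
    algorithm, X, y, k: int = DEFAULT_K_FOLDS, seed: int = 0
) -> EvaluationResult:
    """Stratified k-fold cross-validated AUC for one algorithm.

    ``algorithm`` is an algorithm id or an unfitted :class:`BaseSDM`.  If a
    fold ends up without presences the data is refolded under a new seed,
    erroring after 3 attempts.
    """
    model = make_sdm(algorithm) if isinstance(algorithm, str) else algorithm
    X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
    y = np.asarray(y)
    fold_aucs: list[float] = []
    for attempt in range(3):
        try:
            folds = list(
                StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
                .split(X, y)
            )
            fold_aucs = []
            for train_idx, test_idx in folds:
                y_tr, y_te = y[train_idx], y[test_idx]
                if y_tr.sum() == 0 or y_te.sum() == 0:
                    raise DataError("fold without presences")
                fitted = clone(model).fit(X.iloc[train_idx], y_tr)
                scores = fitted.score_samples(X.iloc[test_idx])
                fold_aucs.append(auc_from_labels(y_te, scores))
            break
        except (DataError, ValueError):
            if attempt == 2:
                raise DataError(
                    f"could not build {k} folds with presences in each"
                )
            continue
    algorithm_id = getattr(model, "algorithm_id", type(model).__name__)
    return EvaluationResult(algorithm_id, fold_aucs, float(np.mean(fold_aucs)))


# ---------------------------------------------------------------------------
# Gating and weighting
# ---------------------------------------------------------------------------

def gate_and_weight(
    mean_aucs: dict[str, float],
    auc_gate: float = DEFAULT_AUC_GATE,
    min_contribution: float = DEFAULT_MIN_CONTRIBUTION,
    weight_mode: str = "auc",
) -> dict[str, float]:
    """Select members and derive normalized AUC-proportional weights.

    Algorithms with mean AUC below ``auc_gate`` are removed; remaining raw
    weights are the AUCs themselves (``weight_mode="auc"``) or the AUC
    excess over 0.5 (``"auc_excess"``), normalized to sum to one.  Members
    whose normalized share is below ``min_contribution`` are then dropped
    one at a time (lowest share first, input-order ties dropped later
    first) and the rest re-normalized, stopping when all shares meet the
    floor — or when every remaining member ties at the same share, in
    which case dropping any one would be arbitrary and all are retained.
    """
    survivors = [a for a, auc in mean_aucs.items() if auc >= auc_gate]
    if not survivors:
        raise GateError(
            f"no algorithm reached the AUC gate {auc_gate}; "
            f"best was {max(mean_aucs.values()):.3f} — review the gate or the data"
        )

    def raw(a: str) -> float:
        if weight_mode == "auc":
            return mean_aucs[a]
        if weight_mode == "auc_excess":
            return max(mean_aucs[a] - 0.5, 0.0)
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")

    while True:
        total = sum(raw(a) for a in survivors)
        if total <= 0:
            raise GateError("surviving weights sum to zero")
        weights = {a: raw(a) / total for a in survivors}
        below = [a for a in survivors if weights[a] < min_contribution]
        if not below:
            return weights
        if len(set(round(weights[a], 15) for a in survivors)) == 1:
            # every member ties; dropping any one would be arbitrary
            return weights
        min_w = min(weights[a] for a in below)
        victim = [a for a in survivors if weights[a] == min_w][-1]
        survivors.remove(victim)


# ---------------------------------------------------------------------------
# Ensemble estimator
# ---------------------------------------------------------------------------

class EnsembleSDM(BaseEstimator):
    """AUC-weighted ensemble of suitability algorithms.

    Parameters
    ----------
    algorithms : sequence of str or (str, BaseSDM), default the four
        built-in learners.  Ids are looked up in the algorithm registry.
    auc_gate : float, default 0.77
        Minimum mean cross-validated AUC for ensemble membership.
    min_contribution : float, default 0.05
        Minimum normalized weight share; lesser members are dropped.
    k : int, default 5
        Cross-validation folds.
    weight_mode : {"auc", "auc_excess"}, default "auc"
    random_state : int, default 0

    Attributes
    ----------
    members_ : dict of id -> fitted BaseSDM
    weights_ : dict of id -> normalized weight (sums to 1)
    cv_results_ : dict of id -> EvaluationResult (all candidates)
    """

    def __init__(
        self,
        algorithms=DEFAULT_ALGORITHMS,
        auc_gate: float = DEFAULT_AUC_GATE,
        min_contribution: float = DEFAULT_MIN_CONTRIBUTION,
        k: int = DEFAULT_K_FOLDS,
        weight_mode: str = "auc",
        random_state: int = 0,
    ):
        self.algorithms = algorithms
        self.auc_gate = auc_gate
        self.min_contribution = min_contribution
        self.k = k
        self.weight_mode = weight_mode
        self.random_state = random_state

    def _roster(self) -> list[tuple[str, BaseSDM]]:
        roster = []
        for item in self.algorithms:
            if isinstance(item, str):
                roster.append((item, make_sdm(item)))
            elif isinstance(item, tuple):
                roster.append((item[0], item[1]))
            else:
                roster.append(
                    (getattr(item, "algorithm_id", type(item).__name__), item)
                )
        return roster

    def fit(self, X, y):
        X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
        y = np.asarray(y)
        if set(np.unique(y)) != {0, 1}:
            raise DataError("y must contain both presences (1) and background (0)")
        self.cv_results_ = {}
        for aid, proto in self._roster():
            res = cross_validate(proto, X, y, k=self.k, seed=self.random_state)
            res.algorithm_id = aid
            res.passed_auc_gate = res.mean_auc >= self.auc_gate
            self.cv_results_[aid] = res
        mean_aucs = {aid: r.mean_auc for aid, r in self.cv_results_.items()}
        self.weights_ = gate_and_weight(
            mean_aucs,
            auc_gate=self.auc_gate,
            min_contribution=self.min_contribution,
            weight_mode=self.weight_mode,
        )
        roster = dict(self._roster())
        self.members_ = {
            aid: clone(roster[aid]).fit(X, y) for aid in self.weights_
        }
        self.variable_names_ = list(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def score_samples(self, X) -> np.ndarray:
        """Ensemble suitability: weighted average of member scores."""
        member_scores = self.member_scores(X)
        total = sum(self.weights_.values())
        out = np.zeros(len(next(iter(member_scores.values()))))
        for aid, s in member_scores.items():
            out += self.weights_[aid] * s
        return out / total

    def member_scores(self, X) -> dict[str, np.ndarray]:
        return {aid: m.score_samples(X) for aid, m in self.members_.items()}

    def holdout_auc(self, X, y) -> float:
        return auc_from_labels(np.asarray(y), self.score_samples(X))

    def evaluation_table(self) -> pd.DataFrame:
        """Per-algorithm AUC report (mean CV AUC, gate flag, weight)."""
        rows = []
        for aid, res in self.cv_results_.items():
            rows.append(
                {
                    "algorithm": aid,
                    "mean_cv_auc": res.mean_auc,
                    "fold_aucs": res.fold_aucs,
                    "passed_auc_gate": res.passed_auc_gate,
                    "weight": self.weights_.get(aid, 0.0),
                }
            )
        return pd.DataFrame(rows)


def ensemble_predict(model: EnsembleSDM, stack: ClimateStack):
    """Weighted-average suitability map over all ensemble members.

    Equivalent to scoring every valid cell: ``S_e = sum(w_i S_i) / sum(w_i)``.
    """
    from .projection import SuitabilityMap

    total = sum(model.weights_.values())
    values = np.zeros(stack.grid.shape, dtype=float)
    for aid, member in model.members_.items():
        m = predict_map(member, stack)
        values += model.weights_[aid] * m.values
        mask = m.mask
    values /= total
    values[mask] = 0.0
    return SuitabilityMap(stack.grid, values, mask)


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def variable_importance(
    model: EnsembleSDM, X, y, n_permutations: int = 10, seed: int = 0
) -> pd.Series:
    """Permutation importance as percentages summing to 100.

    For each variable, its column is permuted ``n_permutations`` times and
    the mean AUC drop recorded per member; drops are averaged across
    members using the ensemble weights, floored at zero, and normalized to
    percentages.
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(X) if not isinstance(X, pd.DataFrame) else X
    y = np.asarray(y)
    names = list(X.columns)
    drops = pd.Series(0.0, index=names)
    total_w = sum(model.weights_.values())
    for aid, member in model.members_.items():
        base = auc_from_labels(y, member.score_samples(X))
        w = model.weights_[aid] / total_w
        for name in names:
            drop = 0.0
            for _ in range(n_permutations):
                Xp = X.copy()
                Xp[name] = rng.permutation(Xp[name].to_numpy())
                drop += base - auc_from_labels(y, member.score_samples(Xp))
            drops[name] += w * drop / n_permutations
    drops = drops.clip(lower=0.0)
    total = drops.sum()
    if total == 0:
        warnings.warn("no variable shows any importance; returning zeros")
        return drops
    return 100.0 * drops / total
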