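"""Shared fixtures: small grids and fitted synthetic worlds.

The expensive fixtures (a 100x100 synthetic world with a fitted ensemble)
are session-scoped so the recovery, invariant and acceptance tests share
one fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from ensdm import (
    EnsembleSDM,
    GridSpec,
    TruthConfig,
    binarize,
    ensemble_predict,
    extract_values,
    find_threshold,
    make_world,
    prune_by_vif,
    split_indices,
)
from ensdm.algorithms import BaseSDM

warnings.filterwarnings("ignore", category=FutureWarning)


class ConstantSDM(BaseSDM):
    """Test helper: a 'model' scoring every row with a fixed value."""

    algorithm_id = "constant"

    def __init__(self, value: float = 0.5):
        self.value = value

    def _fit_presence(self, presences, X, y):
        pass

    def _score(self, M):
        return np.full(M.shape[0], self.value)


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(10, 10, (33.0, -9.0), 0.05)


@dataclass
class FittedWorld:
    world: object
    X: pd.DataFrame
    y: np.ndarray
    retained: list
    train_idx: np.ndarray
    test_idx: np.ndarray
    ensemble: EnsembleSDM
    threshold: float
    binary: object
    suitability: object


def _fit_world(cfg: TruthConfig, n_gcms: int = 1) -> FittedWorld:
    world = make_world(cfg, n_gcms=n_gcms)
    X, y, _ = extract_values(world.stack, world.occurrences)
    retained = prune_by_vif(X).retained
    X = X[retained]
    train_idx, test_idx = split_indices(y, seed=cfg.seed + 1)
    ens = EnsembleSDM(random_state=cfg.seed).fit(X.iloc[train_idx], y[train_idx])
    thr = find_threshold(y[train_idx], ens.score_samples(X.iloc[train_idx]))
    smap = ensemble_predict(ens, world.stack)
    return FittedWorld(
        world, X, y, retained, train_idx, test_idx, ens, thr,
        binarize(smap, thr), smap,
    )


@pytest.fixture(scope="session")
def fitted_world() -> FittedWorld:
    """Default synthetic study system (100x100, 200 presences, 500
    background, seed 1) with a fitted, thresholded ensemble."""
    cfg = TruthConfig(grid=GridSpec(100, 100, (33.0, -9.0), 0.05), seed=1)
    return _fit_world(cfg, n_gcms=3)


@pytest.fixture(scope="session")
def single_signal_world() -> FittedWorld:
    """World where one independent layer carries all the signal."""
    beta = np.zeros(9)
    beta[0] = -6.0
    beta[5] = 9.0  # bio5: first non-collinear layer
    cfg = TruthConfig(
        grid=GridSpec(100, 100, (33.0, -9.0), 0.05), seed=5, beta=beta
    )
    return _fit_world(cfg)
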