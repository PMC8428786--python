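"""Thresholding, suitability classes, GCM consensus and change detection.

A continuous suitability map is reduced to a binary suitable/unsuitable
raster by a probability threshold — either derived from labelled data by
maximizing sensitivity + specificity, or fixed from configuration (the
study design this emulates used 0.34).  The binary map splits further into
five ordered classes, future projections across an ensemble of climate
models are combined by a vote-agreement rule (a cell keeps "suitable" only
when at least 66% of the models agree), and current/future binary pairs
reduce to a loss / stable / gain change map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError
from .geodata import GridSpec

DEFAULT_FIXED_THRESHOLD = 0.34
DEFAULT_AGREEMENT = 0.66

CLASS_NAMES = {
    0: "unsuitable",
    1: "marginal",
    2: "moderate",
    3: "optimal",
    4: "highly suitable",
}
CHANGE_NAMES = {0: "never suitable", 1: "loss", 2: "stable suitable", 3: "gain"}


@dataclass
class SuitabilityMap:
    """Per-cell suitability probability in [0, 1] with a nodata mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise GeometryError("map shape does not match grid")
        off = self.values[~self.mask]
        if off.size and (off.min() < -1e-9 or off.max() > 1 + 1e-9):
            raise ValidationError("suitability values must lie in [0, 1]")


@dataclass
class BinaryMap:
    """0/1 suitable raster; nodata cells are masked."""

    grid: GridSpec
    suitable: np.ndarray
    mask: np.ndarray
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable).astype(np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.suitable.shape != self.grid.shape:
            raise GeometryError("map shape does not match grid")

    @property
    def n_suitable(self) -> int:
        return int(self.suitable[~self.mask].sum())

    def suitable_fraction(self) -> float:
        valid = ~self.mask
        return float(self.suitable[valid].mean())


@dataclass
class ClassMap:
    """Five-class suitability raster (0 unsuitable .. 4 highly suitable)."""

    grid: GridSpec
    classes: np.ndarray
    mask: np.ndarray
    threshold_used: float
    bin_edges: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes).astype(np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.classes.shape != self.grid.shape:
            raise GeometryError("map shape does not match grid")


@dataclass
class ChangeMap:
    """Cellwise change codes: 0 never, 1 loss, 2 stable, 3 gain."""

    grid: GridSpec
    codes: np.ndarray
    mask: np.ndarray


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------

def find_threshold(labels, scores) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are 0, 1 and the midpoints between adjacent distinct sorted
    scores; a point is predicted suitable when its score >= threshold.
    Ties are resolved to the smallest candidate.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must align")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes are required to derive a threshold")
    distinct = np.unique(scores)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2, [1.0]])
    candidates = np.unique(candidates)
    best_t, best_j = 0.0, -np.inf
    for t in candidates:  # ascending, strict improvement => smallest tie wins
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        if sens + spec > best_j + 1e-12:
            best_j, best_t = sens + spec, float(t)
    return best_t


def binarize(map_: SuitabilityMap, threshold: float) -> BinaryMap:
    """Suitable where probability >= threshold; nodata preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must be in [0, 1]")
    suitable = (map_.values >= threshold).astype(np.uint8)
    suitable[map_.mask] = 0
    return BinaryMap(map_.grid, suitable, map_.mask.copy(), threshold_used=threshold)


def classify_five(map_: SuitabilityMap, threshold: float) -> ClassMap:
    """Split [threshold, 1] into four equal-width classes above unsuitable.

    Class 0 covers [0, t); classes 1-4 (marginal, moderate, optimal,
    highly suitable) tile [t, 1] in equal widths, top bin closed.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError("threshold must be in (0, 1)")
    width = (1.0 - threshold) / 4.0
    edges = [threshold + k * width for k in range(5)]  # edges[4] == 1.0
    v = map_.values
    classes = np.zeros(map_.grid.shape, dtype=np.uint8)
    for k in range(1, 5):
        classes[v >= edges[k - 1]] = k
    classes[map_.mask] = 0
    return ClassMap(
        map_.grid, classes, map_.mask.copy(), threshold_used=threshold, bin_edges=edges
    )


# ---------------------------------------------------------------------------
# Consensus and change
# ---------------------------------------------------------------------------

def consensus_votes_needed(n_models: int, agreement: float = DEFAULT_AGREEMENT) -> int:
    """Minimum number of agreeing models: ceil(agreement * n)."""
    x = agreement * n_models
    nearest = round(x)
    return int(nearest) if abs(x - nearest) < 1e-9 else int(math.ceil(x))


def consensus(
    binary_maps: list[BinaryMap], agreement: float = DEFAULT_AGREEMENT
) -> BinaryMap:
    """Vote-agreement combination of per-model binary maps.

    A cell is suitable only when at least ``ceil(agreement * N)`` models
    vote suitable; otherwise it is unsuitable.  (With a two-way split a
    cell may lack any class reaching the agreement level; the rule above
    resolves that conservatively toward unsuitable.)
    """
    if not binary_maps:
        raise ValidationError("need at least one map")
    grid = binary_maps[0].grid
    for m in binary_maps[1:]:
        if m.grid != grid:
            raise GeometryError("consensus inputs must share one grid")
    votes = np.zeros(grid.shape, dtype=int)
    mask = np.zeros(grid.shape, dtype=bool)
    for m in binary_maps:
        votes += m.suitable
        mask |= m.mask
    needed = consensus_votes_needed(len(binary_maps), agreement)
    suitable = (votes >= needed).astype(np.uint8)
    suitable[mask] = 0
    return BinaryMap(grid, suitable, mask)


def change_map(current: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Cellwise (current, future) -> {never, loss, stable, gain}."""
    if current.grid != future.grid:
        raise GeometryError("change map inputs must share one grid")
    cur = current.suitable.astype(int)
    fut = future.suitable.astype(int)
    codes = np.zeros(current.grid.shape, dtype=np.uint8)
    codes[(cur == 1) & (fut == 0)] = 1  # loss
    codes[(cur == 1) & (fut == 1)] = 2  # stable suitable
    codes[(cur == 0) & (fut == 1)] = 3  # gain
    mask = current.mask | future.mask
    codes[mask] = 0
    return ChangeMap(current.grid, codes, mask)
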