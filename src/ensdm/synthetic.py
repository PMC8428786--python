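"""Synthetic study worlds for end-to-end testing of the suitability pipeline.

Real crop-suitability studies start from gridded bioclimatic layers, a set
of farm occurrence points and an ensemble of future climate realizations.
None of those can ship with a test suite, so this module fabricates a world
with a *known* truth:

* spatially smooth, cross-correlated "climate" layers (Gaussian random
  fields, a subset mixed from a common factor so a collinearity pruner has
  genuine work to do);
* a latent logistic suitability surface with a known coefficient vector;
* presence points sampled proportionally to that surface, thinned to one
  per cell, plus uniform background pseudo-absences (default 500, the
  count used in the study design this emulates);
* pseudo-GCM future stacks built as mean shifts of the baseline with
  between-model spread.

Every random draw flows from one root seed through named substreams, so an
identical :class:`TruthConfig` reproduces a bit-identical world.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import ValidationError
from .geodata import (
    BACKGROUND,
    PRESENCE,
    ClimateStack,
    GridSpec,
    OccurrenceSet,
    RegionMask,
)

_SUBSTREAMS = ("layers", "presences", "background", "gcms")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


@dataclass
class TruthConfig:
    """Parameters of a synthetic world.

    beta is the coefficient vector of the latent logistic suitability,
    ``[intercept, b_1, ..., b_n_layers]`` on standardized layers.  The first
    ``ceil(n_layers / 2)`` layers form the collinear block with pairwise
    correlation ``cross_corr``; ``smoothness`` is the Gaussian correlation
    length in cells (1 = white noise).
    """

    grid: GridSpec
    n_layers: int = 8
    smoothness: float = 5.0
    cross_corr: float = 0.95
    beta: np.ndarray | None = None
    n_presence: int = 200
    n_background: int = 500
    seed: int = 0
    layer_prefix: str = "bio"

    def __post_init__(self) -> None:
        if self.beta is None:
            self.beta = default_beta(self.n_layers)
        self.beta = np.asarray(self.beta, dtype=float)
        if not abs(self.cross_corr) < 1:
            raise ValidationError("cross_corr must be in (-1, 1)")
        if self.n_presence < 10:
            raise ValidationError("n_presence must be at least 10")
        if self.beta.shape != (self.n_layers + 1,):
            raise ValidationError(
                f"beta must have length n_layers + 1 = {self.n_layers + 1}"
            )

    @property
    def n_collinear(self) -> int:
        return math.ceil(self.n_layers / 2)

    @property
    def layer_names(self) -> list[str]:
        return [f"{self.layer_prefix}{k + 1}" for k in range(self.n_layers)]


def default_beta(n_layers: int) -> np.ndarray:
    """Default truth coefficients.

    A steep logistic surface emulating a strongly climate-determined crop:
    one collinear layer carries moderate signal (+3), the independent
    layers carry alternating strong effects (+7, -5, +3, -2.5 cycled), and
    the intercept (-6) leaves roughly a quarter of the landscape suitable.
    The steepness concentrates presences in genuinely suitable cells so
    fitted members reach the AUC range reported for such ensembles.
    """
    beta = np.zeros(n_layers + 1)
    beta[0] = -6.0
    c = math.ceil(n_layers / 2)
    beta[1] = 3.0  # one collinear layer carries signal
    cycle = [7.0, -5.0, 3.0, -2.5]
    for j, k in enumerate(range(c + 1, n_layers + 1)):
        beta[k] = cycle[j % len(cycle)]
    return beta


@dataclass
class SyntheticWorld:
    """A complete fabricated study system with known truth."""

    config: TruthConfig
    stack: ClimateStack
    true_suitability: np.ndarray
    occurrences: OccurrenceSet
    regions: RegionMask
    future_stacks: list[ClimateStack] = field(default_factory=list)
    truth_threshold: float = 0.5

    @property
    def true_suitable_fraction(self) -> float:
        valid = ~self.stack.nodata_mask
        return float(
            (self.true_suitability[valid] >= self.truth_threshold).mean()
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    """Standardized Gaussian random field with the given correlation length.

    smoothness <= 1 means white noise; otherwise Gaussian kernel of sigma =
    smoothness cells, truncated at 3 sigma with reflective boundaries.
    """
    field_ = rng.standard_normal(shape)
    if smoothness > 1:
        radius = int(np.ceil(3 * smoothness))
        if min(shape) < 2 * radius + 1:
            raise ValidationError(
                f"grid {shape} too small for smoothing kernel radius {radius}"
            )
        field_ = gaussian_filter(field_, sigma=smoothness, mode="reflect", truncate=3.0)
    field_ -= field_.mean()
    sd = field_.std()
    if sd > 0:
        field_ /= sd
    return field_


def generate_layers(
    cfg: TruthConfig, rng: np.random.Generator | None = None
) -> ClimateStack:
    """Generate the baseline climate stack described by ``cfg``.

    Each layer is a smoothed, standardized Gaussian field.  The first
    ``cfg.n_collinear`` layers are mixed from a shared factor F as
    ``sqrt(rho) * F + sqrt(1 - rho) * G_k`` so their pairwise correlation is
    rho = ``cfg.cross_corr`` in expectation.
    """
    if rng is None:
        rng = _substreams(cfg.seed)["layers"]
    shape = cfg.grid.shape
    rho = cfg.cross_corr
    common = _smooth_field(rng, shape, cfg.smoothness)
    layers: dict[str, np.ndarray] = {}
    for k, name in enumerate(cfg.layer_names):
        g = _smooth_field(rng, shape, cfg.smoothness)
        if k < cfg.n_collinear:
            sign = 1.0 if rho >= 0 else -1.0
            field_ = math.sqrt(abs(rho)) * sign * common + math.sqrt(1 - abs(rho)) * g
        else:
            field_ = g
        field_ = (field_ - field_.mean()) / field_.std()
        layers[name] = field_
    mask = np.zeros(shape, dtype=bool)
    return ClimateStack(cfg.grid, layers, mask)


def make_truth(stack: ClimateStack, beta: np.ndarray) -> np.ndarray:
    """Latent suitability surface: logistic(beta0 + sum_k beta_k * z_k)."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(stack.layers) + 1,):
        raise ValidationError("beta length must be n_layers + 1")
    eta = np.full(stack.grid.shape, beta[0], dtype=float)
    for b, arr in zip(beta[1:], stack.layers.values()):
        eta += b * arr
    return expit(eta)


def sample_occurrences(
    true_map: np.ndarray,
    grid: GridSpec,
    n_presence: int,
    n_background: int = 500,
    seed: int | None = None,
    rng_presence: np.random.Generator | None = None,
    rng_background: np.random.Generator | None = None,
    nodata_mask: np.ndarray | None = None,
) -> OccurrenceSet:
    """Sample presences proportional to suitability, backgrounds uniformly.

    Presence cells are drawn without replacement with probability
    proportional to the true suitability; background cells are drawn
    uniformly from the remaining (non-presence) cells.  Points are placed at
    cell centres.
    """
    if rng_presence is None or rng_background is None:
        streams = _substreams(0 if seed is None else seed)
        rng_presence = rng_presence or streams["presences"]
        rng_background = rng_background or streams["background"]
    true_map = np.asarray(true_map, dtype=float)
    valid = (
        ~np.asarray(nodata_mask, dtype=bool)
        if nodata_mask is not None
        else np.ones(true_map.shape, dtype=bool)
    )
    flat_idx = np.flatnonzero(valid.ravel())
    if n_presence + n_background > flat_idx.size:
        raise ValidationError(
            "not enough valid cells for the requested presences + background"
        )
    weights = true_map.ravel()[flat_idx]
    total = weights.sum()
    if total <= 0:
        raise ValidationError("true suitability sums to zero on valid cells")
    pres_cells = rng_presence.choice(
        flat_idx, size=n_presence, replace=False, p=weights / total
    )
    remaining = np.setdiff1d(flat_idx, pres_cells, assume_unique=False)
    bg_cells = rng_background.choice(remaining, size=n_background, replace=False)
    lons, lats = grid.cell_centers()

    def to_lonlat(cells):
        r, c = np.unravel_index(cells, true_map.shape)
        return lons[c], lats[r]

    plon, plat = to_lonlat(pres_cells)
    blon, blat = to_lonlat(bg_cells)
    return OccurrenceSet.from_arrays(
        np.concatenate([plon, blon]),
        np.concatenate([plat, blat]),
        [PRESENCE] * n_presence + [BACKGROUND] * n_background,
        provenance="synthetic",
    )


def make_future(
    stack: ClimateStack,
    n_gcms: int,
    shift: np.ndarray | dict | float = 0.0,
    spread: np.ndarray | dict | float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[ClimateStack]:
    """Perturb the baseline into ``n_gcms`` future stacks.

    Pseudo-GCM g's layer k is ``baseline_k + shift_k + eps_{g,k}`` with
    ``eps_{g,k} ~ N(0, spread_k^2)`` constant over the grid: every model
    shares the mean climate signal but disagrees by a layer-wide offset.
    """
    if n_gcms < 1:
        raise ValidationError("n_gcms must be >= 1")
    if rng is None:
        rng = _substreams(0 if seed is None else seed)["gcms"]
    names = stack.names

    def per_layer(x) -> np.ndarray:
        if isinstance(x, dict):
            return np.array([float(x.get(n, 0.0)) for n in names])
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 0:
            return np.full(len(names), float(arr))
        if arr.shape != (len(names),):
            raise ValidationError("shift/spread must be scalar or per-layer")
        return arr

    shift_arr = per_layer(shift)
    spread_arr = per_layer(spread)
    futures = []
    for _ in range(n_gcms):
        eps = rng.standard_normal(len(names)) * spread_arr
        layers = {
            n: stack.layers[n] + shift_arr[k] + eps[k]
            for k, n in enumerate(names)
        }
        futures.append(ClimateStack(stack.grid, layers, stack.nodata_mask.copy()))
    return futures


def make_regions(
    grid: GridSpec, n_bands: int = 3, names: list[str] | None = None
) -> RegionMask:
    """Split the grid into horizontal bands of near-equal height, numbered
    1..n_bands from the north; extra rows go to the northernmost bands."""
    if grid.n_rows < n_bands:
        raise ValidationError("grid has fewer rows than requested bands")
    region_id = np.zeros(grid.shape, dtype=int)
    row_blocks = np.array_split(np.arange(grid.n_rows), n_bands)
    for k, rows in enumerate(row_blocks, start=1):
        region_id[rows, :] = k
    if names is None:
        names = [f"band_{k}" for k in range(1, n_bands + 1)]
    if len(names) != n_bands:
        raise ValidationError("need one name per band")
    return RegionMask(grid, region_id, dict(enumerate(names, start=1)))


def make_world(
    cfg: TruthConfig,
    n_gcms: int = 17,
    future_shift: np.ndarray | dict | float | None = None,
    future_spread: np.ndarray | dict | float = 0.15,
    n_regions: int = 3,
) -> SyntheticWorld:
    """Generate a complete synthetic study system.

    The default future scenario shifts each signal-bearing layer against
    the direction that favours the species (a "warming/drying" analogue of
    magnitude 0.4 sd), with a 0.15 sd between-model spread, so projections
    show the net suitability loss typical of such assessments.
    """
    streams = _substreams(cfg.seed)
    stack = generate_layers(cfg, rng=streams["layers"])
    truth = make_truth(stack, cfg.beta)
    occ = sample_occurrences(
        truth,
        cfg.grid,
        cfg.n_presence,
        cfg.n_background,
        rng_presence=streams["presences"],
        rng_background=streams["background"],
    )
    regions = make_regions(cfg.grid, n_bands=n_regions)
    if future_shift is None:
        future_shift = -0.4 * np.sign(cfg.beta[1:])
    futures = make_future(
        stack, n_gcms, shift=future_shift, spread=future_spread, rng=streams["gcms"]
    )
    return SyntheticWorld(cfg, stack, truth, occ, regions, futures)
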