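"""Regional area accounting and change summaries.

Suitable areas are tallied per region in km² and expressed as percentages
of a configurable land-area denominator (for the Malawi study system that
is 94,449 km² of land, excluding water surfaces).  Change summaries report
loss, gain and remaining suitable area per region and in total, conserving
area exactly: remaining = current − loss + gain.

Cell areas come in two modes: ``constant`` (every cell the same area,
default 25 km² for a ~5 km grid) and ``latitude-corrected``
(``(111.320 · Δ)² · cos(lat_center)`` for a Δ-degree cell, shrinking with
latitude as meridians converge).

Rounding for rendered tables is half-up at the printed precision —
areas to the nearest km² unless any row is fractional (then 1 decimal),
percentages to 1 decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .geodata import GridSpec, RegionMask
from .projection import BinaryMap

KM_PER_DEGREE = 111.320
DEFAULT_CELL_AREA_KM2 = 25.0


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (0.05 at 1 dp -> 0.1), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def cell_areas(
    grid: GridSpec,
    mode: str = "constant",
    cell_area_km2: float = DEFAULT_CELL_AREA_KM2,
) -> np.ndarray:
    """Per-cell area in km², shape = grid shape."""
    if mode == "constant":
        return np.full(grid.shape, float(cell_area_km2))
    if mode == "latitude-corrected":
        _, lats = grid.cell_centers()
        side = KM_PER_DEGREE * grid.cell_size
        row_areas = side * side * np.cos(np.deg2rad(lats))
        return np.repeat(row_areas[:, None], grid.n_cols, axis=1)
    raise ValidationError(f"unknown cell-area mode {mode!r}")


@dataclass
class AreaReport:
    """Per-region suitable area and percentage of land area."""

    table: pd.DataFrame  # columns: region, area_km2, percent
    land_area_km2: float
    cell_area_mode: str = "constant"

    @classmethod
    def from_areas(
        cls, areas: dict[str, float], land_area_km2: float, cell_area_mode: str = "constant"
    ) -> "AreaReport":
        """Build a report directly from per-region areas (km²)."""
        rows = [
            {"region": name, "area_km2": float(a), "percent": 100.0 * a / land_area_km2}
            for name, a in areas.items()
        ]
        total = sum(areas.values())
        rows.append(
            {
                "region": "Total",
                "area_km2": float(total),
                "percent": 100.0 * total / land_area_km2,
            }
        )
        return cls(pd.DataFrame(rows), land_area_km2, cell_area_mode)

    @property
    def total_area_km2(self) -> float:
        return float(self.table.loc[self.table["region"] == "Total", "area_km2"].iloc[0])

    @property
    def total_percent(self) -> float:
        return float(self.table.loc[self.table["region"] == "Total", "percent"].iloc[0])

    def regional_areas(self) -> dict[str, float]:
        body = self.table[self.table["region"] != "Total"]
        return dict(zip(body["region"], body["area_km2"]))


def area_by_region(
    binary: BinaryMap,
    regions: RegionMask,
    cell_area: np.ndarray | float = DEFAULT_CELL_AREA_KM2,
    land_area_km2: float | None = None,
    cell_area_mode: str = "constant",
) -> AreaReport:
    """Tally suitable area per region.

    ``land_area_km2`` defaults to the total area of all cells inside the
    study area (region id > 0 and not nodata).
    """
    if binary.grid != regions.grid:
        raise GeometryError("map and regions must share one grid")
    area = (
        np.full(binary.grid.shape, float(cell_area))
        if np.isscalar(cell_area)
        else np.asarray(cell_area, dtype=float)
    )
    if area.shape != binary.grid.shape:
        raise GeometryError("cell area raster shape mismatch")
    inside = (regions.region_id > 0) & ~binary.mask
    if land_area_km2 is None:
        land_area_km2 = float(area[inside].sum())
    suitable = (binary.suitable == 1) & inside
    areas = {}
    for rid in regions.ids:
        name = regions.region_names[rid]
        areas[name] = float(area[suitable & (regions.region_id == rid)].sum())
    return AreaReport.from_areas(areas, land_area_km2, cell_area_mode)


@dataclass
class ChangeReport:
    """Per-region loss / gain / remaining accounting for one scenario."""

    table: pd.DataFrame  # region, current, loss, gain, remaining (+ percents)
    land_area_km2: float
    scenario: str = ""

    def row(self, region: str) -> pd.Series:
        return self.table.set_index("region").loc[region]


def change_summary(
    current_areas: dict[str, float] | AreaReport,
    loss_areas: dict[str, float],
    gain_areas: dict[str, float] | None = None,
    land_area_km2: float | None = None,
    scenario: str = "",
) -> ChangeReport:
    """Assemble a change report from per-region current / loss / gain areas.

    remaining = current − loss + gain, per region and in total; all
    percentages are against the land-area denominator.
    """
    if isinstance(current_areas, AreaReport):
        if land_area_km2 is None:
            land_area_km2 = current_areas.land_area_km2
        current_areas = current_areas.regional_areas()
    if land_area_km2 is None:
        raise ValidationError("land_area_km2 is required")
    gain_areas = gain_areas or {}
    regions = list(current_areas)
    missing = set(loss_areas) - set(regions)
    if missing:
        raise ValidationError(f"loss regions not in current report: {sorted(missing)}")
    rows = []
    for name in regions:
        cur = float(current_areas[name])
        loss = float(loss_areas.get(name, 0.0))
        gain = float(gain_areas.get(name, 0.0))
        if loss < 0 or gain < 0:
            raise ValidationError("loss and gain areas must be non-negative")
        remaining = cur - loss + gain
        rows.append(
            {
                "region": name,
                "current_km2": cur,
                "loss_km2": loss,
                "gain_km2": gain,
                "remaining_km2": remaining,
            }
        )
    total = {k: sum(r[k] for r in rows) for k in rows[0] if k != "region"}
    rows.append({"region": "Total", **total})
    df = pd.DataFrame(rows)
    for col in ("loss", "gain", "remaining"):
        df[f"{col}_percent"] = 100.0 * df[f"{col}_km2"] / land_area_km2
    return ChangeReport(df, land_area_km2, scenario)


def render_report(
    report: AreaReport | ChangeReport,
    area_decimals: int | None = None,
    percent_decimals: int = 1,
) -> str:
    """Render a report as CSV text with half-up rounding.

    Areas print as integers unless any value is fractional at the printed
    precision (then 1 decimal); percentages print to ``percent_decimals``.
    """
    df = report.table.copy()
    area_cols = [c for c in df.columns if c.endswith("km2") or c == "area_km2"]
    pct_cols = [c for c in df.columns if "percent" in c]
    if area_decimals is None:
        fractional = any(
            abs(v - round(v)) > 1e-9 for c in area_cols for v in df[c].to_numpy()
        )
        area_decimals = 1 if fractional else 0
    for c in area_cols:
        df[c] = [
            f"{round_half_up(v, area_decimals):,.{area_decimals}f}" for v in df[c]
        ]
    for c in pct_cols:
        df[c] = [f"{round_half_up(v, percent_decimals):.{percent_decimals}f}" for v in df[c]]
    return df.to_csv(index=False)
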