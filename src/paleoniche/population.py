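"""Carrying-capacity population estimates: P = D-bar x A.

Density maps apply a fitted log-log density-NPP equation cell-wise to an
NPP layer inside a suitability mask, giving individuals/100 km².  The
sustainable population of an interval is the mean density over the
suitable area times that area; with density in individuals/100 km² and
area in km² this is ``P = D-bar x A / 100``, which on an equal-area grid
equals the cell-wise sum exactly.  Headline numbers conventionally use
the lower-bound (minimum) density map.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foragers import RegressionFit
from .grids import GridConformanceError, Layer, Mask, cell_areas

__all__ = ["PopulationEstimate", "density_map", "total_population",
           "interval_series", "band_count"]


@dataclass(frozen=True)
class PopulationEstimate:
    interval_id: str
    area_km2: float
    mean_density: float  # individuals / 100 km² over the suitable area
    total: float         # individuals

    def __post_init__(self) -> None:
        if self.area_km2 < 0:
            raise ValueError("negative area")


def density_map(npp: Layer, fit: RegressionFit, mask: Mask,
                bound: str = "lower") -> Layer:
    """Density layer D = 10^(intercept + slope * log10 NPP) on masked cells.

    Cells inside the mask with non-positive or missing NPP become nodata
    (counted in a warning); everything outside the mask is nodata.
    """
    if not npp.grid.conformal_with(mask.grid):
        raise GridConformanceError("NPP layer and mask are not conformal")
    values = np.full(npp.grid.shape, np.nan)
    sel = mask.values
    npp_sel = npp.values[sel]
    ok = np.isfinite(npp_sel) & (npp_sel > 0)
    if (~ok).sum():
        warnings.warn(f"{int((~ok).sum())} masked cells with NPP <= 0 set to nodata")
    d = np.full(npp_sel.shape, np.nan)
    d[ok] = fit.predict_density(npp_sel[ok])
    values[sel] = d
    return Layer(npp.grid, values, name=f"density_{bound}")


def total_population(density: Layer, mask: Mask,
                     areas: Layer | None = None,
                     interval_id: str = "") -> PopulationEstimate:
    """Total sustainable population over a suitability mask.

    ``A`` sums cell areas over the mask (nodata-density cells excluded),
    ``D-bar`` is the unweighted mean density there, and
    ``P = D-bar x A / 100`` — identical to the cell-wise sum
    ``sum_i D_i a_i / 100`` on an equal-area grid.
    """
    if areas is None:
        areas = cell_areas(density.grid)
    if not density.grid.conformal_with(mask.grid):
        raise GridConformanceError("density layer and mask are not conformal")
    sel = mask.values & np.isfinite(density.values)
    if not sel.any():
        warnings.warn("empty (or all-nodata) mask: population is zero")
        return PopulationEstimate(interval_id, 0.0, 0.0, 0.0)
    a = float(areas.values[sel].sum())
    dbar = float(density.values[sel].mean())
    return PopulationEstimate(interval_id, a, dbar, dbar * a / 100.0)


def interval_series(estimates_lower, estimates_upper=None) -> tuple[pd.DataFrame, dict]:
    """Tabulate per-interval estimates and summarise extremes.

    Accepts lists of :class:`PopulationEstimate` (lower bound, and
    optionally upper bound, matched by interval id).  The summary names
    the maximum and minimum interval by lower-bound population and the
    percent drop from maximum to minimum.
    """
    upper_by_id = {e.interval_id: e for e in (estimates_upper or [])}
    rows = []
    for est in estimates_lower:
        row = {"interval": est.interval_id, "area_km2": est.area_km2,
               "mean_density_lower": est.mean_density, "p_lower": est.total}
        up = upper_by_id.get(est.interval_id)
        if up is not None:
            row["mean_density_upper"] = up.mean_density
            row["p_upper"] = up.total
        rows.append(row)
    table = pd.DataFrame(rows)
    imax = table["p_lower"].idxmax()
    imin = table["p_lower"].idxmin()
    p_max = float(table.loc[imax, "p_lower"])
    p_min = float(table.loc[imin, "p_lower"])
    summary = {
        "max_interval": table.loc[imax, "interval"],
        "min_interval": table.loc[imin, "interval"],
        "p_max": p_max,
        "p_min": p_min,
        "percent_drop": 100.0 * (1.0 - p_min / p_max) if p_max > 0 else 0.0,
    }
    return table, summary


def band_count(p: float, band_size: float = 25.0) -> int:
    """Whole hunter-gatherer bands sustainable at population ``p``.

    25 individuals is the classic modal band size; the count is
    ``floor(P / band_size)``.
    """
    if band_size <= 0:
        raise ValueError("band_size must be positive")
    if p < 0:
        raise ValueError("population must be non-negative")
    return int(math.floor(p / band_size))
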