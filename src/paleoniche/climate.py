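"""Interval climate stacks and Miami-model net primary productivity.

Marine-isotope substages (the analysis intervals, e.g. "MIS12b") can span
several 10-ka palaeoclimate time slices; interval climates are per-cell
arithmetic means over the member slices.  NPP is estimated from mean
annual temperature (BIO1, °C) and total annual precipitation (BIO12,
mm/yr) with the Miami model, taking the minimum of a temperature-limited
and a precipitation-limited production curve:

    NPP_T = 3000 / (1 + exp(1.315 - 0.119 * T))
    NPP_P = 3000 * (1 - exp(-0.000664 * P))
    NPP   = min(NPP_T, NPP_P)        [g dry matter / m^2 / yr]

The constants are Lieth's (1972) canonical parameterisation; the 3000
g DM/m²·yr asymptote is never exceeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GridConformanceError, Layer, Mask, RasterGrid

__all__ = ["ClimateStack", "TimeInterval", "aggregate_interval", "miami_npp",
           "MIAMI_MAX_NPP"]

MIAMI_MAX_NPP = 3000.0  # g dry matter / m^2 / yr
_MIAMI_T_A = 1.315
_MIAMI_T_B = 0.119
_MIAMI_P_K = 0.000664


@dataclass
class ClimateStack:
    """Named covariate layers (BIO*, elevation, ...) sharing one grid."""

    grid: RasterGrid
    layers: dict[str, Layer]
    slice_id: str = ""

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            if not layer.grid.conformal_with(self.grid):
                raise GridConformanceError(f"layer {name!r} not conformal with stack grid")

    def __getitem__(self, name: str) -> Layer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def subset(self, names) -> "ClimateStack":
        return ClimateStack(self.grid, {n: self.layers[n] for n in names}, self.slice_id)


@dataclass(frozen=True)
class TimeInterval:
    """An analysis interval aggregating one or more time slices."""

    id: str
    slice_ids: tuple[str, ...]
    duration_ka: float = 10.0

    def __post_init__(self) -> None:
        if not self.slice_ids:
            raise ValueError(f"interval {self.id!r} needs at least one slice")


def aggregate_interval(stacks_by_slice: dict[str, ClimateStack],
                       interval: TimeInterval) -> ClimateStack:
    """Per-cell arithmetic mean of each variable over the interval's slices.

    A cell is nodata in the output if it is nodata in *any* member slice
    (partial means would bias interval climates along shifting coastlines).
    """
    missing = [s for s in interval.slice_ids if s not in stacks_by_slice]
    if missing:
        raise KeyError(f"interval {interval.id!r}: missing slices {missing}")
    stacks = [stacks_by_slice[s] for s in interval.slice_ids]
    grid = stacks[0].grid
    names = stacks[0].names
    for st in stacks[1:]:
        if not st.grid.conformal_with(grid):
            raise GridConformanceError("slice stacks are not conformal")
        if st.names != names:
            raise ValueError("slice stacks carry different variables")
    out: dict[str, Layer] = {}
    for name in names:
        vals = np.stack([st[name].values for st in stacks])
        mean = vals.mean(axis=0)  # NaN if any slice is NaN
        out[name] = Layer(grid, mean, name=name)
    return ClimateStack(grid, out, slice_id=interval.id)


def miami_npp(bio1: Layer, bio12: Layer) -> Layer:
    """Miami-model NPP layer from BIO1 (°C) and BIO12 (mm/yr)."""
    if not bio1.grid.conformal_with(bio12.grid):
        raise GridConformanceError("BIO1 and BIO12 layers are not conformal")
    t = bio1.values
    p = bio12.values
    npp_t = MIAMI_MAX_NPP / (1.0 + np.exp(_MIAMI_T_A - _MIAMI_T_B * t))
    npp_p = MIAMI_MAX_NPP * (1.0 - np.exp(-_MIAMI_P_K * p))
    npp = np.minimum(npp_t, npp_p)
    return Layer(bio1.grid, npp, name="npp")


def interval_mask(masks_by_slice: dict[str, Mask], interval: TimeInterval) -> Mask:
    """Onshore mask of an interval: cells onshore in every member slice."""
    masks = [masks_by_slice[s] for s in interval.slice_ids]
    out = masks[0]
    for m in masks[1:]:
        out = out & m
    return out
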