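"""Synthetic world generator: climate stacks, sites and a forager table.

Every downstream stage is testable offline against this module's known
ground truth.  It emulates the *statistical structure* of the real
inputs — spatially autocorrelated bioclimatic layers on an equal-area
grid with an elevation-derived coastline, glacial/interglacial time
slices aggregated into analysis intervals, archaeological assemblages
drawn from a known Gibbs niche, and a Binford-style ethnographic table
with planted log-log density-NPP laws — not actual palaeoclimate.

Layers are Gaussian random fields (white noise smoothed with a Gaussian
kernel of the requested correlation length, then renormalised to the
requested mean/sd).  Cold slices shift BIO1/BIO12 by a fixed glacial
offset.  A few deliberately collinear extra BIO variables are derived
from the six primary covariates to exercise covariate selection.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .climate import ClimateStack, TimeInterval, aggregate_interval, interval_mask
from .grids import Layer, Mask, RasterGrid

__all__ = [
    "LayerSpec",
    "TrueNiche",
    "WorldSpec",
    "EthnoSimSpec",
    "gen_climate_stacks",
    "gen_sites",
    "gen_ethno_table",
    "build_world",
]


@dataclass(frozen=True)
class LayerSpec:
    """Mean, spatial s.d. and correlation length (in cells) of one layer."""

    mean: float
    sd: float
    corr_length: float  # Gaussian-kernel sigma in cells; > 0

    def __post_init__(self) -> None:
        if self.corr_length < 0:
            raise ValueError("correlation length must be >= 0")


# Primary covariates: annual mean temperature (°C), diurnal range (°C),
# annual range (°C), annual precipitation (mm/yr), precipitation
# seasonality (CV %), elevation (m; ~40% of cells below sea level).
DEFAULT_LAYERS: dict[str, LayerSpec] = {
    "BIO1": LayerSpec(8.0, 4.0, 15.0),
    "BIO2": LayerSpec(9.0, 2.0, 12.0),
    "BIO7": LayerSpec(25.0, 5.0, 12.0),
    "BIO12": LayerSpec(800.0, 250.0, 15.0),
    "BIO15": LayerSpec(40.0, 12.0, 12.0),
    "elevation": LayerSpec(120.0, 400.0, 10.0),
}


@dataclass(frozen=True)
class TrueNiche:
    """Known Gaussian (log-quadratic Gibbs) niche over two covariates.

    log-suitability  eta = -((v1 - c1)/w1)^2 - ((v2 - c2)/w2)^2 ; site
    cells are drawn with probability proportional to exp(eta) over the
    onshore cells.
    """

    var1: str = "BIO1"
    var2: str = "BIO12"
    center1: float = 10.0
    center2: float = 900.0
    width1: float = 6.0
    width2: float = 400.0

    def eta(self, stack: ClimateStack) -> np.ndarray:
        v1 = stack[self.var1].values
        v2 = stack[self.var2].values
        return (-(((v1 - self.center1) / self.width1) ** 2)
                - ((v2 - self.center2) / self.width2) ** 2)

    def suitability(self, stack: ClimateStack, mask: Mask) -> Layer:
        """Normalised true suitability (sums to 1 over onshore cells)."""
        e = np.exp(self.eta(stack))
        vals = np.where(mask.values, e, np.nan)
        vals = vals / np.nansum(vals)
        return Layer(stack.grid, vals, name="true_suitability")


def _default_intervals() -> tuple[TimeInterval, ...]:
    return (
        TimeInterval("W1", ("s0", "s1"), 20.0),   # interglacial
        TimeInterval("C1", ("s2", "s3"), 20.0),   # glacial
        TimeInterval("W2", ("s4",), 10.0),
        TimeInterval("C2", ("s5",), 10.0),
    )


@dataclass(frozen=True)
class WorldSpec:
    """Complete recipe for a synthetic study region."""

    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 5000.0  # metres; equal-area grid
    origin: tuple[float, float] = (3_200_000.0, 3_000_000.0)
    crs_id: str = "EPSG:3035"
    seed: int = 0
    layers: dict[str, LayerSpec] = field(default_factory=lambda: dict(DEFAULT_LAYERS))
    slice_offsets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "s0": (0.0, 0.0), "s1": (-1.0, -50.0),
            "s2": (-8.0, -300.0), "s3": (-7.0, -250.0),
            "s4": (1.0, 50.0), "s5": (-6.0, -200.0),
        })  # slice -> (BIO1 offset °C, BIO12 offset mm)
    intervals: tuple[TimeInterval, ...] = field(default_factory=_default_intervals)
    slice_noise_frac: float = 0.1  # per-slice field perturbation, x layer sd
    include_collinear: bool = True
    true_niche: TrueNiche = field(default_factory=TrueNiche)
    n_sites: int = 46
    n_assemblages: int = 68
    dated_fraction: float = 33.0 / 68.0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("degenerate grid")
        for iv in self.intervals:
            for s in iv.slice_ids:
                if s not in self.slice_offsets:
                    raise ValueError(f"interval {iv.id} references unknown slice {s}")

    @property
    def grid(self) -> RasterGrid:
        return RasterGrid(self.n_rows, self.n_cols, self.cell_size,
                          self.origin, self.crs_id)

    @property
    def slice_ids(self) -> tuple[str, ...]:
        return tuple(self.slice_offsets)


def _grf(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian random field."""
    white = rng.standard_normal(shape)
    if sigma <= 0:
        f = white
    else:
        f = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


# Collinear extras derived (with mild noise) from the primary covariates;
# they must be caught by the correlation/VIF preselection.
_COLLINEAR_RECIPES = {
    "BIO6": ("BIO1", 1.2, -8.0, 0.05),    # min temp of coldest month ~ BIO1
    "BIO10": ("BIO1", 0.9, 9.0, 0.05),    # mean temp warmest quarter ~ BIO1
    "BIO13": ("BIO12", 0.18, 10.0, 0.05),  # wettest-month precipitation
    "BIO16": ("BIO12", 0.45, 15.0, 0.05),  # wettest-quarter precipitation
    "BIO4": ("BIO7", 28.0, 80.0, 0.05),   # temperature seasonality ~ range
}


def gen_climate_stacks(spec: WorldSpec) -> tuple[dict[str, ClimateStack], dict[str, Mask]]:
    """Generate per-slice climate stacks and onshore masks.

    Returns ``(stacks_by_slice, masks_by_slice)``.  Onshore cells are
    those with elevation > 0; elevation (hence the coastline) is shared
    across slices.  BIO1/BIO12 carry the per-slice glacial offsets plus
    a small per-slice field perturbation.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    shape = grid.shape
    base = {name: ls.mean + ls.sd * _grf(rng, shape, ls.corr_length)
            for name, ls in spec.layers.items()}
    elev = base["elevation"]
    onshore = elev > 0
    if onshore.sum() < 0.05 * elev.size:
        raise ValueError("coastline rule left almost no onshore cells")
    stacks: dict[str, ClimateStack] = {}
    masks: dict[str, Mask] = {}
    for sid in spec.slice_ids:
        d_t, d_p = spec.slice_offsets[sid]
        layers: dict[str, Layer] = {}
        for name, ls in spec.layers.items():
            vals = base[name].copy()
            if name != "elevation" and spec.slice_noise_frac > 0:
                vals = vals + spec.slice_noise_frac * ls.sd * _grf(
                    rng, shape, ls.corr_length)
            if name == "BIO1":
                vals = vals + d_t
            elif name == "BIO12":
                vals = np.maximum(vals + d_p, 0.0)
            layers[name] = Layer(grid, vals, name=name)
        if spec.include_collinear:
            for name, (src, a, b, noise_frac) in _COLLINEAR_RECIPES.items():
                src_vals = layers[src].values
                noise = noise_frac * abs(a) * spec.layers[src].sd * _grf(
                    rng, shape, spec.layers[src].corr_length)
                layers[name] = Layer(grid, a * src_vals + b + noise, name=name)
        stacks[sid] = ClimateStack(grid, layers, slice_id=sid)
        masks[sid] = Mask(grid, onshore.copy())
    return stacks, masks


def gen_sites(stacks: dict[str, ClimateStack], masks: dict[str, Mask],
              spec: WorldSpec, true_niche: TrueNiche | None = None,
              seed: int | None = None) -> pd.DataFrame:
    """Draw an assemblage table from the true niche.

    Site cells are sampled (without replacement) over onshore cells with
    probability proportional to the true suitability of the pooled
    climate; assemblages are distributed over sites (some sites carry
    several), dated with probability ``spec.dated_fraction`` and dated
    ones assigned an interval (weights favour the first interval so at
    least one interval has a usable training sample).  Undated
    assemblages carry interval "uncorrelated".

    Columns: site_id, assemblage_id, x, y, interval, dated.
    """
    niche = true_niche or spec.true_niche
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    pooled = aggregate_interval(
        stacks, TimeInterval("pooled", tuple(stacks), 1.0))
    mask_all = masks[next(iter(masks))]
    for m in masks.values():
        mask_all = mask_all & m
    suit = niche.suitability(pooled, mask_all).values
    flat_idx = np.flatnonzero(np.nan_to_num(suit, nan=0.0) > 0)
    probs = suit.ravel()[flat_idx]
    probs = probs / probs.sum()
    if spec.n_sites > flat_idx.size:
        raise ValueError("n_sites exceeds candidate onshore cells")
    chosen = rng.choice(flat_idx, size=spec.n_sites, replace=False, p=probs)
    rows_i, cols_i = np.unravel_index(chosen, mask_all.grid.shape)
    cx, cy = mask_all.grid.cell_centers()
    xs = cx[rows_i, cols_i]
    ys = cy[rows_i, cols_i]
    # distribute assemblages: every site gets one, extras go to random sites
    owners = np.concatenate([
        np.arange(spec.n_sites),
        rng.integers(0, spec.n_sites, size=spec.n_assemblages - spec.n_sites),
    ])
    interval_ids = [iv.id for iv in spec.intervals]
    weights = np.array([2.0] + [1.0] * (len(interval_ids) - 1))
    weights = weights / weights.sum()
    records = []
    for a_idx, s_idx in enumerate(owners):
        dated = bool(rng.random() < spec.dated_fraction)
        interval = (str(rng.choice(interval_ids, p=weights)) if dated
                    else "uncorrelated")
        records.append({
            "site_id": f"site{s_idx:03d}",
            "assemblage_id": f"asm{a_idx:03d}",
            "x": float(xs[s_idx]), "y": float(ys[s_idx]),
            "interval": interval, "dated": int(dated),
        })
    df = pd.DataFrame(records)
    # guarantee one interval with a usable training sample
    counts = df[df["dated"] == 1]["interval"].value_counts()
    if len(counts) and counts.max() < 10:
        top = counts.idxmax()
        movable = df.index[(df["dated"] == 1) & (df["interval"] != top)]
        need = min(10 - int(counts.max()), len(movable))
        df.loc[movable[:need], "interval"] = top
    return df


@dataclass(frozen=True)
class EthnoSimSpec:
    """Planted per-strategy log10 density-NPP laws for the forager table.

    Defaults emulate a Holarctic forager compilation: NPP spanning polar
    desert to temperate forest (log10 NPP 1.4-3.4), moderate residual
    scatter (~0.3 dex) around the per-strategy power laws.  Densities in
    individuals/100 km², NPP in g DM/m²·yr.
    """

    intercepts: dict[str, float] = field(default_factory=lambda: {
        "hunters": -2.362, "gatherers": -4.0253, "fishers": -1.5})
    slopes: dict[str, float] = field(default_factory=lambda: {
        "hunters": 0.9427, "gatherers": 1.8485, "fishers": 0.6})
    residual_sd: dict[str, float] = field(default_factory=lambda: {
        "hunters": 0.30, "gatherers": 0.35, "fishers": 0.35})
    n: dict[str, int] = field(default_factory=lambda: {
        "hunters": 60, "gatherers": 65, "fishers": 90})
    lognpp_range: tuple[float, float] = (1.4, 3.4)
    diet_centroids: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "hunters": (70.0, 15.0, 15.0),
            "fishers": (20.0, 65.0, 15.0),
            "gatherers": (25.0, 15.0, 60.0),
        })  # (pct_hunt, pct_fish, pct_gather) centroids
    diet_jitter: float = 6.0
    latitude_range: tuple[float, float] = (31.0, 69.0)
    trade_fraction: float = 0.10
    horseback_fraction: float = 0.15  # among hunters
    alt_density_fraction: float = 0.0
    alt_density_log_sd: float = 0.05

    def __post_init__(self) -> None:
        for s, n in self.n.items():
            if n < 3:
                raise ValueError(f"need n >= 3 per strategy, got {n} for {s}")
        for s, sd in self.residual_sd.items():
            if sd < 0:
                raise ValueError("residual sd must be >= 0")


def gen_ethno_table(spec: EthnoSimSpec = EthnoSimSpec(), seed: int = 0) -> pd.DataFrame:
    """Generate a Binford-style forager table with known ground truth.

    ``log10 D = intercept + slope * log10 NPP + N(0, sd)`` per strategy;
    diet percentages are jittered around the strategy centroid and sum
    to exactly 100.  The ``true_strategy`` column records the planted
    class (the analysis pipeline re-derives labels by k-means).
    """
    rng = np.random.default_rng(seed)
    rows = []
    gid = 0
    for strat, n in spec.n.items():
        lognpp = rng.uniform(*spec.lognpp_range, size=n)
        logd = (spec.intercepts[strat] + spec.slopes[strat] * lognpp
                + spec.residual_sd[strat] * rng.standard_normal(n))
        c = np.array(spec.diet_centroids[strat])
        for i in range(n):
            diet = c + spec.diet_jitter * rng.standard_normal(3)
            diet = np.clip(diet, 1.0, None)
            diet = 100.0 * diet / diet.sum()
            diet[2] = 100.0 - diet[0] - diet[1]  # exact sum
            horse = (strat == "hunters") and (rng.random() < spec.horseback_fraction)
            density = 10.0 ** logd[i]
            alt = np.nan
            if rng.random() < spec.alt_density_fraction:
                alt = density * 10.0 ** (spec.alt_density_log_sd
                                         * rng.standard_normal())
            rows.append({
                "group": f"{strat[:-1]}_{gid:03d}",
                "latitude": float(rng.uniform(*spec.latitude_range)),
                "density": float(density),
                "alt_density": float(alt) if np.isfinite(alt) else np.nan,
                "npp": float(10.0 ** lognpp[i]),
                "pct_hunt": float(diet[0]),
                "pct_fish": float(diet[1]),
                "pct_gather": float(diet[2]),
                "trade_dependent": bool(rng.random() < spec.trade_fraction),
                "horseback": bool(horse),
                "true_strategy": strat,
            })
            gid += 1
    return pd.DataFrame(rows)


def build_world(spec: WorldSpec):
    """Convenience: stacks, masks, interval climates/masks and site table.

    Returns a dict with keys ``stacks``, ``masks``, ``interval_stacks``,
    ``interval_masks``, ``sites``.
    """
    stacks, masks = gen_climate_stacks(spec)
    interval_stacks = {iv.id: aggregate_interval(stacks, iv) for iv in spec.intervals}
    interval_masks = {iv.id: interval_mask(masks, iv) for iv in spec.intervals}
    sites = gen_sites(stacks, masks, spec)
    return {
        "spec": spec,
        "stacks": stacks,
        "masks": masks,
        "interval_stacks": interval_stacks,
        "interval_masks": interval_masks,
        "sites": sites,
    }
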