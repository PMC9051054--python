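"""Occurrence sampling: site buffers, thinning, folds and background.

Archaeological site locations are expanded into their 10-km surroundings
(one-way daily foraging range), thinned to one point per raster cell,
restricted to onshore cells, and grouped so that a site and its buffer
always share a cross-validation fold (random folds would leak spatially
autocorrelated points between train and test).  Background points are a
fixed uniform sample of onshore cells shared by every candidate model,
which keeps AICc/AUC comparisons across candidates well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateStack
from .grids import Mask

__all__ = [
    "buffer_sample",
    "multi_occupation_expand",
    "grouped_kfold",
    "sample_background",
]


def multi_occupation_expand(assemblages: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an assemblage table into training and validation site records.

    Sites occupied in several intervals become one (site, interval) record
    per dated assemblage, each carrying its own interval's environmental
    conditions.  Assemblages not correlated to an interval
    (``interval == "uncorrelated"`` or ``dated == 0``) go to the external
    validation set.

    Expects columns: site_id, x, y, interval, dated (0/1).
    Returns ``(training, validation)`` frames.
    """
    df = assemblages.copy()
    dated = df["dated"].astype(bool) & (df["interval"] != "uncorrelated")
    training = df[dated].reset_index(drop=True)
    validation = df[~dated].reset_index(drop=True)
    return training, validation


def buffer_sample(sites: pd.DataFrame, stack: ClimateStack, mask: Mask,
                  radius_km: float = 10.0) -> pd.DataFrame:
    """Presence sample: onshore cells within ``radius_km`` of each site.

    Distance is centre-to-centre in the projected (equal-area) CRS.  A
    cell falling in several buffers is kept once and attributed to the
    nearest site.  Sites whose buffers are entirely offshore contribute
    nothing (with a warning).

    Returns a frame with cell_row, cell_col, site_id, distance_m and one
    column per covariate in ``stack``.
    """
    grid = stack.grid
    radius = radius_km * 1000.0 if not grid.is_geographic else radius_km / 111.195
    cx, cy = grid.cell_centers()
    best: dict[tuple[int, int], tuple[float, object]] = {}
    for rec in sites.itertuples(index=False):
        # candidate window around the site
        r0, c0 = grid.index_of(rec.x, rec.y)
        halo = int(np.ceil(radius / grid.cell_size)) + 1
        rows = range(max(0, r0 - halo), min(grid.n_rows, r0 + halo + 1))
        cols = range(max(0, c0 - halo), min(grid.n_cols, c0 + halo + 1))
        found = False
        for i in rows:
            for j in cols:
                if not mask.values[i, j]:
                    continue
                d = float(np.hypot(cx[i, j] - rec.x, cy[i, j] - rec.y))
                if d > radius:
                    continue
                found = True
                cell = (i, j)
                if cell not in best or d < best[cell][0]:
                    best[cell] = (d, rec.site_id)
        if not found:
            warnings.warn(f"site {rec.site_id!r}: buffer entirely offshore, no points")
    rows_out = []
    for (i, j), (d, site_id) in sorted(best.items()):
        row = {"cell_row": i, "cell_col": j, "site_id": site_id, "distance_m": d}
        for name in stack.names:
            row[name] = stack[name].values[i, j]
        rows_out.append(row)
    cols = ["cell_row", "cell_col", "site_id", "distance_m", *stack.names]
    return pd.DataFrame(rows_out, columns=cols)


def grouped_kfold(sample: pd.DataFrame, k: int = 5, seed: int = 0) -> np.ndarray:
    """Site-grouped fold labels: all points of a site share one fold.

    Sites are shuffled with ``seed`` and dealt round-robin, so per-fold
    site counts differ by at most one.  Returns an int array aligned with
    ``sample`` rows.
    """
    sites = pd.unique(sample["site_id"])
    if k > len(sites):
        raise ValueError(f"k={k} exceeds the number of distinct sites ({len(sites)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    fold_of = {sites[idx]: pos % k for pos, idx in enumerate(order)}
    return sample["site_id"].map(fold_of).to_numpy(dtype=int)


def sample_background(mask: Mask, stack: ClimateStack, n: int = 10_000,
                      seed: int = 0) -> pd.DataFrame:
    """Uniform sample of ``n`` distinct onshore cells with their covariates.

    The same background table must be reused across all candidate models
    of a calibration grid (same seed → identical table).
    """
    onshore = np.flatnonzero(mask.values.ravel())
    if n > onshore.size:
        raise ValueError(f"requested {n} background cells, only {onshore.size} onshore")
    rng = np.random.default_rng(seed)
    chosen = onshore if n == onshore.size else rng.choice(onshore, size=n, replace=False)
    chosen = np.sort(chosen)
    rows, cols = np.unravel_index(chosen, mask.grid.shape)
    data = {"cell_row": rows, "cell_col": cols}
    for name in stack.names:
        data[name] = stack[name].values[rows, cols]
    return pd.DataFrame(data)
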