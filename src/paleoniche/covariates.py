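"""Covariate preselection: pairwise-correlation filter and iterative VIF.

Candidate bioclimatic covariates are highly collinear; before feeding a
feature-expanding niche model they are reduced in two stages:

1. Any pair with Pearson *or* Spearman |r| above a threshold (default
   0.9) loses its lower-priority member.  "Priority" operationalises
   "retain the more general variable" as an explicit user-supplied
   ordering (annual means before ranges before seasonality before
   quarter/month extremes; elevation last to be removed).
2. Remaining covariates are pruned by iterating: compute each VIF_j
   = 1 / (1 - R²_j) from regressing covariate j on all others, remove
   the argmax while max VIF >= threshold (default 5).

Both stages emit a :class:`SelectionReport` recording every removal and
its triggering statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SelectionReport", "correlation_filter", "vif_iterative",
           "sample_covariate_table", "DEFAULT_PRIORITY"]

# Annual means > ranges > seasonality > quarterly/monthly extremes;
# elevation is last-removable (bottom of the removal preference = top priority end).
DEFAULT_PRIORITY = (
    "elevation",
    "BIO1", "BIO12",
    "BIO2", "BIO7",
    "BIO4", "BIO15", "BIO3",
    "BIO5", "BIO6", "BIO8", "BIO9", "BIO10", "BIO11",
    "BIO13", "BIO14", "BIO16", "BIO17", "BIO18", "BIO19",
)


@dataclass
class SelectionReport:
    retained: list[str]
    steps: list[dict]  # each: {"removed": name, "statistic": str, "value": float}
    vif_table: pd.DataFrame | None = None

    @property
    def removed(self) -> list[str]:
        return [s["removed"] for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def sample_covariate_table(stacks, mask_by_slice, names=None, n=10_000,
                           seed: int = 0) -> pd.DataFrame:
    """Sample onshore cells pooled across time slices into a covariate table.

    ``stacks`` maps slice id -> ClimateStack, ``mask_by_slice`` maps slice
    id -> onshore Mask.  Rows with any nodata are dropped before sampling.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for sid, stack in stacks.items():
        cols = names or stack.names
        onshore = mask_by_slice[sid].values
        data = {c: stack[c].values[onshore] for c in cols}
        frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True).dropna()
    if len(table) > n:
        idx = rng.choice(len(table), size=n, replace=False)
        table = table.iloc[np.sort(idx)].reset_index(drop=True)
    return table


def _priority_key(priority_order):
    order = {name: i for i, name in enumerate(priority_order)}

    def key(name: str) -> int:
        if name not in order:
            raise ValueError(f"priority_order does not cover covariate {name!r}")
        return order[name]

    return key


def correlation_filter(table: pd.DataFrame, priority_order=DEFAULT_PRIORITY,
                       r_threshold: float = 0.9) -> SelectionReport:
    """Drop the lower-priority member of every over-correlated pair.

    A covariate is retained iff it is not correlated (Pearson or Spearman
    |r| > ``r_threshold``) with any *retained* higher-priority covariate;
    scanning in priority order makes the result independent of column
    order.  Constant columns (undefined r) are removed with a warning.
    """
    key = _priority_key(priority_order)
    cols = sorted(table.columns, key=key)
    steps: list[dict] = []
    retained: list[str] = []
    for name in cols:
        x = table[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; removed")
            steps.append({"removed": name, "statistic": "constant", "value": np.nan})
            continue
        hit = None
        for kept in retained:
            y = table[kept].to_numpy(dtype=float)
            pear = abs(stats.pearsonr(x, y).statistic)
            spear = abs(stats.spearmanr(x, y).statistic)
            r = max(pear, spear)
            if r > r_threshold:
                hit = (kept, r)
                break
        if hit is None:
            retained.append(name)
        else:
            steps.append({
                "removed": name,
                "statistic": f"|r| vs {hit[0]}",
                "value": float(hit[1]),
            })
    return SelectionReport(retained=retained, steps=steps)


def _vifs(x: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1-R²_j) from OLS of column j on the others plus intercept."""
    n, p = x.shape
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = x[:, j]
        design = np.hstack([ones, np.delete(x, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_iterative(table: pd.DataFrame, vif_threshold: float = 5.0,
                  priority_order=DEFAULT_PRIORITY) -> SelectionReport:
    """Iteratively remove the max-VIF covariate until all VIF < threshold.

    Exact linear dependence yields VIF = +inf and is removed first.  Ties
    in the argmax are broken by *reverse* priority (the less general
    variable goes).
    """
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two covariates")
    if len(table) <= len(cols):
        raise ValueError("need more rows than covariates")
    key = _priority_key(priority_order)
    steps: list[dict] = []
    while len(cols) >= 2:
        x = table[cols].to_numpy(dtype=float)
        vifs = _vifs(x)
        vmax = vifs.max()
        if vmax < vif_threshold:
            break
        worst = [cols[j] for j in range(len(cols)) if vifs[j] == vmax]
        victim = max(worst, key=key)  # reverse priority among ties
        steps.append({"removed": victim, "statistic": "VIF", "value": float(vmax)})
        cols.remove(victim)
    x = table[cols].to_numpy(dtype=float)
    vifs = _vifs(x)
    vif_table = pd.DataFrame({
        "covariate": cols,
        "vif": vifs,
        "tolerance": 1.0 / vifs,
        "r_squared": 1.0 - 1.0 / vifs,
    })
    return SelectionReport(retained=cols, steps=steps, vif_table=vif_table)


def select_covariates(table: pd.DataFrame, priority_order=DEFAULT_PRIORITY,
                      r_threshold: float = 0.9,
                      vif_threshold: float = 5.0) -> SelectionReport:
    """Correlation filter followed by iterative VIF; one merged report."""
    rep1 = correlation_filter(table, priority_order, r_threshold)
    rep2 = vif_iterative(table[rep1.retained], vif_threshold, priority_order)
    return SelectionReport(retained=rep2.retained, steps=rep1.steps + rep2.steps,
                           vif_table=rep2.vif_table)
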