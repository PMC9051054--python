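"""Ethnographic forager layer: strategy classification and density-NPP fits.

Recent hunter-gatherer groups (Binford-style table: latitude, population
density in individuals/100 km², Miami-model NPP in g dry matter/m²·yr,
and diet percentages) anchor the density predictions.  Preparation
keeps groups above 30° N, drops trade-dependent societies, and averages
duplicate density estimates.  Groups are classified into hunters /
fishers / gatherers by k-means on the diet composition (fishers are not
used downstream: reliance on fishing as the staple requires technology
unavailable in the Lower Palaeolithic).

Per strategy, three log10-log10 OLS fits are produced: the *average* fit
through all points, and *lower*/*upper* envelope fits through the
per-0.1-LOGNPP-bin minima and maxima of log density.  The lower and
upper hunter equations later turn NPP maps into density maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

__all__ = [
    "RegressionFit",
    "EnvelopeFit",
    "prepare_ethno",
    "classify_strategy",
    "loglog_fit",
    "outlier_exclusion",
    "envelope_fit",
    "compare_slopes",
    "fit_strategy_table",
]

STRATEGIES = ("hunters", "fishers", "gatherers")
_DIET_COLS = ("pct_hunt", "pct_fish", "pct_gather")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of LOGD on LOGNPP (log10 scales)."""

    intercept: float
    slope: float
    r: float
    p: float
    n: int

    @property
    def r_squared(self) -> float:
        return self.r**2

    @property
    def df_resid(self) -> int:
        return self.n - 2

    def predict_logd(self, lognpp) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(lognpp, dtype=float)

    def predict_density(self, npp) -> np.ndarray:
        """Density in individuals/100 km² from NPP in g DM/m²·yr."""
        return 10.0 ** self.predict_logd(np.log10(np.asarray(npp, dtype=float)))


@dataclass(frozen=True)
class EnvelopeFit:
    lower: RegressionFit
    upper: RegressionFit
    bin_width: float
    n_bins: int


def prepare_ethno(raw: pd.DataFrame, min_latitude: float = 30.0) -> pd.DataFrame:
    """Filter and derive the working forager table.

    Keeps latitude >= ``min_latitude`` (the 30° N parallel rule,
    boundary inclusive), drops trade-dependent groups and rows with
    non-positive density or NPP, averages ``density`` with
    ``alt_density`` where the latter is present, and adds ``logd`` /
    ``lognpp`` (log10) columns.
    """
    df = raw.copy()
    df = df[df["latitude"] >= min_latitude]
    if "trade_dependent" in df:
        df = df[~df["trade_dependent"].astype(bool)]
    if "alt_density" in df:
        alt = df["alt_density"]
        df["density"] = np.where(alt.notna() & (alt > 0),
                                 (df["density"] + alt) / 2.0, df["density"])
    bad = (df["density"] <= 0) | (df["npp"] <= 0)
    df = df[~bad]
    df = df.reset_index(drop=True)
    df["logd"] = np.log10(df["density"])
    df["lognpp"] = np.log10(df["npp"])
    return df


def classify_strategy(table: pd.DataFrame, k: int = 3, seed: int = 0) -> pd.Series:
    """K-means labels on diet composition: hunters / fishers / gatherers.

    Clusters are named by matching centroids to diet components
    (hunting, fishing, gathering) with a maximum-weight assignment, so
    each strategy name is used exactly once.  k-means++ with 25 restarts
    and a fixed seed makes the labels effectively deterministic.
    """
    x = table[list(_DIET_COLS)].to_numpy(dtype=float)
    if k > len(np.unique(x, axis=0)):
        raise ValueError("k exceeds the number of distinct diet rows")
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    labels = km.fit_predict(x)
    # centroids x components score matrix; maximise total assigned weight
    score = km.cluster_centers_[:, :3]
    rows, cols = linear_sum_assignment(-score)
    name_of = {int(r): STRATEGIES[int(c)] for r, c in zip(rows, cols)}
    return pd.Series([name_of[l] for l in labels], index=table.index,
                     name="strategy")


def loglog_fit(records: pd.DataFrame) -> RegressionFit:
    """OLS of log10 density on log10 NPP with Pearson r and two-sided p."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = records["lognpp"].to_numpy(dtype=float)
    y = records["logd"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in LOGNPP")
    res = stats.linregress(x, y)
    return RegressionFit(intercept=float(res.intercept), slope=float(res.slope),
                         r=float(res.rvalue), p=float(res.pvalue), n=len(x))


def outlier_exclusion(records: pd.DataFrame, fit: RegressionFit,
                      level: float = 0.95) -> tuple[pd.DataFrame, list, RegressionFit]:
    """Drop points outside the OLS 95% prediction interval; single pass.

    Returns (kept records, excluded group names, refit on kept records).
    """
    x = records["lognpp"].to_numpy(dtype=float)
    y = records["logd"].to_numpy(dtype=float)
    n = len(x)
    resid = y - fit.predict_logd(x)
    s2 = float(resid @ resid) / (n - 2)
    sxx = float(((x - x.mean()) ** 2).sum())
    se_pred = np.sqrt(s2 * (1.0 + 1.0 / n + (x - x.mean()) ** 2 / sxx))
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 2)
    outside = np.abs(resid) > tcrit * se_pred
    kept = records[~outside].reset_index(drop=True)
    excluded = records.loc[outside, "group"].tolist() if "group" in records else \
        records.index[outside].tolist()
    return kept, excluded, loglog_fit(kept)


def envelope_fit(records: pd.DataFrame, bin_width: float = 0.1) -> EnvelopeFit:
    """Lower/upper envelope regressions through per-bin extreme densities.

    LOGNPP is binned with width ``bin_width`` anchored at
    ``floor(min/bin_width) * bin_width``; each non-empty bin contributes
    its maximum-LOGD point to the upper fit and its minimum-LOGD point
    to the lower fit (a singleton bin contributes the same point to
    both).  Requires at least 3 non-empty bins.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    x = records["lognpp"].to_numpy(dtype=float)
    anchor = np.floor(x.min() / bin_width) * bin_width
    bin_idx = np.floor((x - anchor) / bin_width).astype(int)
    lows, highs = [], []
    for b in np.unique(bin_idx):
        sub = records[bin_idx == b]
        lows.append(sub.loc[sub["logd"].idxmin()])
        highs.append(sub.loc[sub["logd"].idxmax()])
    if len(lows) < 3:
        raise ValueError(f"only {len(lows)} non-empty bins; need >= 3")
    lower = loglog_fit(pd.DataFrame(lows))
    upper = loglog_fit(pd.DataFrame(highs))
    return EnvelopeFit(lower=lower, upper=upper, bin_width=bin_width,
                       n_bins=len(lows))


def compare_slopes(records_a: pd.DataFrame, records_b: pd.DataFrame) -> dict:
    """Homogeneity-of-slopes test between two record sets.

    Returns the residual variance-ratio F (two-sided p) of the two
    separate fits and the t statistic (two-sided p) of the
    group x LOGNPP interaction coefficient in the pooled model.
    """
    fits = []
    resids = []
    for rec in (records_a, records_b):
        fit = loglog_fit(rec)
        fits.append(fit)
        x = rec["lognpp"].to_numpy(dtype=float)
        y = rec["logd"].to_numpy(dtype=float)
        resids.append(y - fit.predict_logd(x))
    v_a = float(resids[0] @ resids[0]) / (len(resids[0]) - 2)
    v_b = float(resids[1] @ resids[1]) / (len(resids[1]) - 2)
    f_stat = v_a / v_b
    df_a, df_b = len(resids[0]) - 2, len(resids[1]) - 2
    p_f = 2 * min(stats.f.sf(f_stat, df_a, df_b), stats.f.cdf(f_stat, df_a, df_b))
    # pooled model with interaction
    x = np.concatenate([records_a["lognpp"], records_b["lognpp"]]).astype(float)
    y = np.concatenate([records_a["logd"], records_b["logd"]]).astype(float)
    g = np.concatenate([np.zeros(len(records_a)), np.ones(len(records_b))])
    design = np.column_stack([np.ones_like(x), x, g, g * x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = len(y) - design.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(design.T @ design)
    t_stat = float(coef[3] / np.sqrt(cov[3, 3]))
    p_t = 2 * stats.t.sf(abs(t_stat), dof)
    return {"F": float(f_stat), "p_F": float(p_f), "t": t_stat, "p_t": float(p_t)}


def fit_strategy_table(prepared: pd.DataFrame, strategies=("hunters", "gatherers"),
                       bin_width: float = 0.1,
                       exclude_outliers: bool = True) -> pd.DataFrame:
    """Average + envelope fits per strategy, one row per (strategy, kind).

    ``prepared`` must carry a ``strategy`` column (see
    :func:`classify_strategy`).  Outliers beyond the 95% prediction
    interval of the average fit are removed (single pass) before the
    envelope fits, mirroring the published procedure.
    """
    rows = []
    for strat in strategies:
        sub = prepared[prepared["strategy"] == strat].reset_index(drop=True)
        avg = loglog_fit(sub)
        if exclude_outliers:
            sub, _, avg = outlier_exclusion(sub, avg)
        env = envelope_fit(sub, bin_width=bin_width)
        for kind, fit in (("average", avg), ("lower", env.lower), ("upper", env.upper)):
            rows.append({"strategy": strat, "kind": kind,
                         "intercept": fit.intercept, "slope": fit.slope,
                         "r": fit.r, "p": fit.p, "r_squared": fit.r_squared,
                         "n": fit.n})
    return pd.DataFrame(rows)
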