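"""Candidate evaluation and selection for the niche-model calibration grid.

Candidates vary over feature-class sets (L, LQ, LQH, LQP, LQHP, LQHPT)
and regularisation multipliers (0.2-4.0 plus the 1.0 default, nine in
all); each is scored with

* AICc (Warren & Seifert convention: the likelihood is the product of
  raw normalised densities at the presences, k counts non-zero
  coefficients),
* OR.10, the mean over folds of the fraction of test presences scoring
  strictly below the 10%-lower-percentile threshold of the training
  presences,
* AUC, the mean rank-based test AUC over folds (ties count one half).

Percentiles use the lower (inverted-CDF) convention shared with
suitability binarisation.  All candidates must score against one shared
background sample for the AICc/AUC comparison to be meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .climate import ClimateStack
from .grids import Mask
from .maxent import (
    FEATURE_CLASS_SETS,
    REGULARIZATION_MULTIPLIERS,
    MaxEntModel,
    expand_features,
    fit_maxent,
    lower_quantile,
    make_feature_spec,
)
from .occurrence import sample_background

__all__ = [
    "auc",
    "omission_rate_10",
    "aicc",
    "run_candidate_grid",
    "select_model",
    "background_sensitivity",
    "external_validation",
    "covariate_importance",
]


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(random presence outscores random background).

    Equivalent to the Mann-Whitney U statistic scaled to [0, 1]; tied
    scores count one half.  Invariant under strictly monotone transforms
    of the scores.
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score sets must be non-empty")
    combined = np.concatenate([pres, back])
    ranks = stats.rankdata(combined)
    u = ranks[: pres.size].sum() - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * back.size))


def omission_rate_10(train_presence_scores, test_presence_scores,
                     q: float = 0.10) -> float:
    """Fraction of test presences strictly below the q-lower-percentile
    threshold of the training presences."""
    thr = lower_quantile(train_presence_scores, q)
    test = np.asarray(test_presence_scores, dtype=float)
    if test.size == 0:
        raise ValueError("empty test presence scores")
    return float((test < thr).mean())


def aicc(model: MaxEntModel, presence_features: np.ndarray,
         background_features: np.ndarray) -> float:
    """Small-sample AICc of a fitted model on its presence sample.

    ``lnL = sum_presences ln(raw density)`` with the raw densities
    renormalised over ``background_features`` (the shared grid
    background), ``k`` = non-zero coefficients.  Returns +inf (with a
    warning) when n <= k + 1, ranking the candidate last.
    """
    n = presence_features.shape[0]
    k = model.k_params
    if n <= k + 1:
        warnings.warn(f"AICc undefined for n={n}, k={k}; returning +inf")
        return np.inf
    eta_bg = background_features @ model.lam
    mx = eta_bg.max()
    log_z = mx + np.log(np.exp(eta_bg - mx).sum())
    lnl = float((presence_features @ model.lam - log_z).sum())
    return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class CandidateResult:
    classes: str
    rm: float
    model: MaxEntModel
    aicc: float
    or10: float
    auc: float


def run_candidate_grid(sample: pd.DataFrame, background: pd.DataFrame,
                       covariates, folds: np.ndarray,
                       feature_sets=FEATURE_CLASS_SETS,
                       rms=REGULARIZATION_MULTIPLIERS,
                       knots: int = 50, max_iter: int = 500,
                       tol: float = 1e-5) -> tuple[pd.DataFrame, dict]:
    """Fit and score every (feature set, RM) candidate.

    ``sample`` is the occurrence table (with covariate columns and
    site-grouped ``folds`` labels aligned to its rows); ``background``
    the shared background table.  Returns the metrics frame (one row per
    candidate, 6 x 9 = 54 with the default grid) and a dict of fitted
    full-data models keyed by (classes, rm).
    """
    covariates = list(covariates)
    pres_cov = sample[covariates]
    bg_cov = background[covariates]
    pooled = pd.concat([pres_cov, bg_cov], ignore_index=True)
    fold_ids = np.unique(folds)
    rows = []
    models: dict[tuple[str, float], MaxEntModel] = {}
    for classes in feature_sets:
        spec = make_feature_spec(pooled, classes, covariates, knots=knots)
        fp_all = expand_features(pres_cov, spec)
        fb_all = expand_features(bg_cov, spec)
        for rm in rms:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = fit_maxent(fp_all, fb_all, spec, rm=rm,
                                       max_iter=max_iter, tol=tol)
                    a = aicc(model, fp_all, fb_all)
                    or10s, aucs = [], []
                    for f in fold_ids:
                        train = fp_all[folds != f]
                        test = fp_all[folds == f]
                        if train.shape[0] == 0 or test.shape[0] == 0:
                            continue
                        fold_model = fit_maxent(train, fb_all, spec, rm=rm,
                                                max_iter=max_iter, tol=tol)
                        s_train = fold_model.raw(train)
                        s_test = fold_model.raw(test)
                        s_bg = fold_model.raw(fb_all)
                        or10s.append(omission_rate_10(s_train, s_test))
                        aucs.append(auc(s_test, s_bg))
                ok = True
            except (ValueError, FloatingPointError) as exc:  # candidate failed
                warnings.warn(f"candidate ({classes}, {rm}) failed: {exc}")
                ok = False
            if ok:
                models[(classes, rm)] = model
                rows.append({
                    "classes": classes, "rm": rm, "aicc": a,
                    "or10": float(np.mean(or10s)), "auc": float(np.mean(aucs)),
                    "k_params": model.k_params, "converged": model.converged,
                })
            else:
                rows.append({"classes": classes, "rm": rm, "aicc": np.nan,
                             "or10": np.nan, "auc": np.nan, "k_params": 0,
                             "converged": False})
    metrics = pd.DataFrame(rows)
    finite = metrics["aicc"].replace(np.inf, np.nan)
    metrics["delta_aicc"] = metrics["aicc"] - finite.min()
    return metrics, models


def select_model(metrics: pd.DataFrame, rule: str = "compromise",
                 delta_aicc_cap: float = 2000.0) -> pd.Series:
    """Pick a candidate row from the metrics table.

    Rules: ``min_aicc``; ``min_or10``; ``compromise`` (default) =
    minimise OR.10 among candidates with AUC >= the grid median and
    delta-AICc <= ``delta_aicc_cap``, formalising a judgement call that
    trades a mid-field AICc for low omission and high AUC.
    """
    ok = metrics.dropna(subset=["aicc", "or10", "auc"])
    if ok.empty:
        raise ValueError("no converged candidates")
    if rule == "min_aicc":
        return ok.loc[ok["aicc"].idxmin()]
    if rule == "min_or10":
        return ok.loc[ok["or10"].idxmin()]
    if rule == "compromise":
        qualified = ok[(ok["auc"] >= ok["auc"].median())
                       & (ok["delta_aicc"] <= delta_aicc_cap)]
        if qualified.empty:
            qualified = ok
        return qualified.loc[qualified["or10"].idxmin()]
    raise ValueError(f"unknown selection rule {rule!r}")


def background_sensitivity(mask: Mask, stack: ClimateStack, ns,
                           seed: int = 0, reps: int = 20) -> pd.DataFrame:
    """Stability of background sampling vs sample size.

    For each n the maximum (over covariates) Kolmogorov-Smirnov distance
    between the sampled and the full-mask covariate distributions,
    averaged over ``reps`` seeded draws.  The distribution is considered
    stable once the distance flattens out (empirically n > 1000).
    """
    ns = list(ns)
    if sorted(ns) != ns:
        raise ValueError("ns must be ascending")
    onshore = mask.values
    full = {c: np.sort(stack[c].values[onshore]) for c in stack.names}
    n_cells = int(onshore.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        if n > n_cells:
            raise ValueError(f"n={n} exceeds {n_cells} onshore cells")
        dists = []
        for _ in range(reps):
            sub_seed = int(rng.integers(2**31))
            bg = sample_background(mask, stack, n=n, seed=sub_seed)
            d = max(stats.ks_2samp(bg[c].to_numpy(), full[c]).statistic
                    for c in stack.names)
            dists.append(d)
        rows.append({"n": n, "mean_max_ks": float(np.mean(dists)),
                     "sd_max_ks": float(np.std(dists))})
    return pd.DataFrame(rows)


def external_validation(masks_by_interval: dict[str, Mask],
                        undated: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Fraction of undated assemblages falling inside a suitability mask.

    An assemblage counts as inside if its cell is suitable in at least
    one of its candidate intervals (column ``candidate_intervals``, an
    iterable of interval ids; missing/empty means all intervals).
    Offshore cells are flagged and dropped from the denominator.
    """
    rows = []
    any_grid = next(iter(masks_by_interval.values())).grid
    for rec in undated.itertuples(index=False):
        r, c = any_grid.index_of(rec.x, rec.y)
        if not any_grid.contains(r, c):
            rows.append({"site_id": rec.site_id, "status": "offshore", "inside": False})
            continue
        cands = getattr(rec, "candidate_intervals", None)
        if cands is None or (isinstance(cands, float) and np.isnan(cands)) or not len(cands):
            cands = list(masks_by_interval)
        onshore_any = False
        inside = False
        for iv in cands:
            m = masks_by_interval[iv]
            onshore_any = True
            if m.values[r, c]:
                inside = True
                break
        status = "ok" if onshore_any else "offshore"
        rows.append({"site_id": rec.site_id, "status": status, "inside": inside})
    report = pd.DataFrame(rows)
    valid = report[report["status"] == "ok"]
    frac = float(valid["inside"].mean()) if len(valid) else 0.0
    return frac, report


def covariate_importance(model: MaxEntModel, presence: pd.DataFrame,
                         background: pd.DataFrame, seed: int = 0,
                         reps: int = 10) -> pd.DataFrame:
    """Permutation importance and model contribution per covariate.

    Permutation importance is the mean drop in training AUC when one
    covariate's values are shuffled jointly across presence + background
    (seeded, ``reps`` repeats).  Contribution is the sum over that
    covariate's features of |lambda_j| x feature s.d. over the
    background, normalised to percent.
    """
    spec = model.feature_spec
    cov = list(spec.covariates)
    fp = expand_features(presence[cov], spec)
    fb = expand_features(background[cov], spec)
    base_auc = auc(model.raw(fp), model.raw(fb))
    names = spec.feature_names()
    sds = fb.std(axis=0)
    contrib = np.zeros(len(cov))
    for j, fname in enumerate(names):
        body = fname.split(":", 1)[1]
        for i, c in enumerate(cov):
            if body == c or body.startswith(f"{c}@") or f"{c}*" in body or body.endswith(f"*{c}"):
                contrib[i] += abs(model.lam[j]) * sds[j]
    total = contrib.sum()
    contrib_pct = 100 * contrib / total if total > 0 else contrib
    rng = np.random.default_rng(seed)
    drops = []
    n_p = len(presence)
    for c in cov:
        drop = []
        for _ in range(reps):
            pooled = pd.concat([presence[cov], background[cov]], ignore_index=True)
            pooled[c] = rng.permutation(pooled[c].to_numpy())
            f_all = expand_features(pooled, spec)
            drop.append(base_auc - auc(model.raw(f_all[:n_p]), model.raw(f_all[n_p:])))
        drops.append(float(np.mean(drop)))
    out = pd.DataFrame({"covariate": cov, "permutation_importance": drops,
                        "contribution_pct": contrib_pct})
    return out.sort_values("permutation_importance", ascending=False,
                           ignore_index=True)
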