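"""Maximum-entropy presence-background niche model, written from scratch.

The model is a Gibbs density over environmental cells,

    q_lambda(i) = exp(lambda . f(x_i)) / Z_lambda,

normalised over a background sample, fitted by minimising the
L1-penalised negative presence log-likelihood

    J(lambda) = log Z_lambda - mean_presence(lambda . f)
                + sum_j beta_j |lambda_j|,

whose optimum satisfies the feature-matching (KKT) conditions
``|E_q[f_j] - mean_presence[f_j]| <= beta_j`` for every feature, with
equality in the sign direction of every active coefficient.  The
per-feature penalty is ``beta_j = RM * beta0_class(m) * s_j / sqrt(m)``
(s_j = feature s.d. over the background, m = presence count, beta0 the
class-default tables of MaxEnt 3.4.4, RM the user regularisation
multiplier).

Covariates are min-max scaled to [0, 1] on the training sample and
expanded into feature classes L (linear), Q (quadratic), P (pairwise
products), H (forward + reverse hinges on a knot grid) and T (step
indicators on a knot grid).  Prediction clamps projection covariates to
the training range by default, and reports the cloglog output
``1 - exp(-exp(H_bg) * raw)`` of MaxEnt 3.4.4 (raw and logistic are also
available).

The optimiser is FISTA (accelerated proximal gradient with backtracking
and restarts); correctness is defined by the KKT contract above, not by
the algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateStack
from .grids import GridConformanceError, Layer, Mask

__all__ = [
    "FeatureSpec",
    "MaxEntModel",
    "BinarizationResult",
    "make_feature_spec",
    "expand_features",
    "fit_maxent",
    "predict",
    "predict_table",
    "binarize",
    "lower_quantile",
]

FEATURE_CLASS_SETS = ("L", "LQ", "LQH", "LQP", "LQHP", "LQHPT")
REGULARIZATION_MULTIPLIERS = (0.2, 0.4, 0.6, 0.8, 1.0, 1.5, 2.0, 3.0, 4.0)

# MaxEnt class-default beta0 interpolation tables (presence count -> beta0).
_BETA0_TABLES = {
    "L": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "Q": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "P": ([0, 10, 17, 30, 100], [1.3, 0.8, 0.5, 0.25, 0.05]),
    "H": ([0], [0.5]),
    "T": ([0, 100], [2.0, 1.0]),
}


def _beta0(feature_class: str, m: int) -> float:
    xs, ys = _BETA0_TABLES[feature_class]
    return float(np.interp(m, xs, ys))


def lower_quantile(values, q: float) -> float:
    """Empirical quantile under the lower / inverted-CDF convention.

    The q-quantile of n sorted values is the ceil(q*n)-th order statistic
    (the first one when ``q*n <= 1``).  Shared by suitability
    binarisation and the 10%-omission threshold.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    k = max(1, int(np.ceil(q * v.size)))
    return float(v[k - 1])


@dataclass(frozen=True)
class FeatureSpec:
    """Feature expansion description, frozen at training time."""

    classes: str  # subset/ordering of "LQHPT", e.g. "LQP"
    covariates: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    knots: int = 50

    def __post_init__(self) -> None:
        if not self.classes or any(c not in "LQHPT" for c in self.classes):
            raise ValueError(f"invalid feature classes {self.classes!r}")
        if ("H" in self.classes or "T" in self.classes) and self.knots < 2:
            raise ValueError("hinge/threshold classes need knots >= 2")

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    def feature_names(self) -> list[str]:
        names: list[str] = []
        d = self.n_covariates
        cov = self.covariates
        if "L" in self.classes:
            names += [f"L:{c}" for c in cov]
        if "Q" in self.classes:
            names += [f"Q:{c}" for c in cov]
        if "P" in self.classes:
            names += [f"P:{cov[a]}*{cov[b]}" for a in range(d) for b in range(a + 1, d)]
        if "H" in self.classes:
            ts = np.arange(self.knots) / self.knots
            names += [f"Hf:{c}@{t:.4f}" for c in cov for t in ts]
            ts = np.arange(1, self.knots + 1) / self.knots
            names += [f"Hr:{c}@{t:.4f}" for c in cov for t in ts]
        if "T" in self.classes:
            ts = np.arange(1, self.knots) / self.knots
            names += [f"T:{c}@{t:.4f}" for c in cov for t in ts]
        return names

    def feature_classes(self) -> np.ndarray:
        """Class character per expanded column, aligned with feature_names."""
        out: list[str] = []
        d = self.n_covariates
        if "L" in self.classes:
            out += ["L"] * d
        if "Q" in self.classes:
            out += ["Q"] * d
        if "P" in self.classes:
            out += ["P"] * (d * (d - 1) // 2)
        if "H" in self.classes:
            out += ["H"] * (2 * self.knots * d)
        if "T" in self.classes:
            out += ["T"] * ((self.knots - 1) * d)
        return np.array(out)

    @property
    def n_features(self) -> int:
        return len(self.feature_classes())


def make_feature_spec(table: pd.DataFrame, classes: str, covariates=None,
                      knots: int = 50) -> FeatureSpec:
    """Build a FeatureSpec with scaling ranges from a training table.

    ``table`` should hold the pooled presence + background covariates.
    Zero-variance covariates are dropped with a warning.
    """
    covariates = list(covariates or table.columns)
    keep, mins, maxs = [], [], []
    for c in covariates:
        x = table[c].to_numpy(dtype=float)
        lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
        if hi <= lo:
            warnings.warn(f"covariate {c!r} has zero variance; dropped from features")
            continue
        keep.append(c)
        mins.append(lo)
        maxs.append(hi)
    if not keep:
        raise ValueError("no informative covariates remain")
    return FeatureSpec(classes=classes, covariates=tuple(keep),
                       mins=tuple(mins), maxs=tuple(maxs), knots=knots)


def _scale(spec: FeatureSpec, table: pd.DataFrame, clamp: bool) -> np.ndarray:
    cols = []
    for c, lo, hi in zip(spec.covariates, spec.mins, spec.maxs):
        z = (table[c].to_numpy(dtype=float) - lo) / (hi - lo)
        if clamp:
            z = np.clip(z, 0.0, 1.0)
        cols.append(z)
    return np.column_stack(cols)


def expand_features(table: pd.DataFrame, spec: FeatureSpec,
                    clamp: bool = True) -> np.ndarray:
    """Expand a covariate table into the scaled feature matrix.

    Column layout follows :meth:`FeatureSpec.feature_names`: per class,
    L gives d columns, Q another d, P the C(d,2) pairwise products, H
    two hinge families of ``knots`` columns per covariate (forward
    ``max(0, z-t)/(1-t)`` at t = k/knots, k=0..knots-1; reverse
    ``max(0, t-z)/t`` at t = k/knots, k=1..knots), and T the ``knots-1``
    step indicators ``1[z > t]`` at interior knots.  All features lie in
    [0, 1] when inputs are clamped.
    """
    z = _scale(spec, table, clamp)
    d = z.shape[1]
    blocks: list[np.ndarray] = []
    if "L" in spec.classes:
        blocks.append(z)
    if "Q" in spec.classes:
        blocks.append(z**2)
    if "P" in spec.classes:
        prods = [z[:, a] * z[:, b] for a in range(d) for b in range(a + 1, d)]
        if prods:
            blocks.append(np.column_stack(prods))
    if "H" in spec.classes:
        tf = np.arange(spec.knots) / spec.knots
        fwd = np.maximum(0.0, z[:, :, None] - tf[None, None, :]) / (1.0 - tf)
        blocks.append(fwd.reshape(z.shape[0], -1))
        tr = np.arange(1, spec.knots + 1) / spec.knots
        rev = np.maximum(0.0, tr[None, None, :] - z[:, :, None]) / tr
        blocks.append(rev.reshape(z.shape[0], -1))
    if "T" in spec.classes:
        tt = np.arange(1, spec.knots) / spec.knots
        step = (z[:, :, None] > tt[None, None, :]).astype(float)
        blocks.append(step.reshape(z.shape[0], -1))
    return np.hstack(blocks)


@dataclass
class MaxEntModel:
    """Fitted maximum-entropy model (coefficients + normalisation)."""

    feature_spec: FeatureSpec
    lam: np.ndarray           # one coefficient per expanded feature
    rm: float                 # regularisation multiplier, > 0
    beta: np.ndarray          # per-feature L1 penalty actually applied
    log_z: float              # log normaliser over the training background
    entropy: float            # entropy of the fitted background distribution
    n_presence: int
    converged: bool = True
    kkt_residual: float = np.nan

    def linear_predictor(self, features: np.ndarray) -> np.ndarray:
        return features @ self.lam

    def raw(self, features: np.ndarray) -> np.ndarray:
        """Raw (Gibbs) density relative to the training normaliser."""
        return np.exp(self.linear_predictor(features) - self.log_z)

    def output(self, features: np.ndarray, kind: str = "cloglog") -> np.ndarray:
        raw = self.raw(features)
        if kind == "raw":
            return raw
        if kind == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        if kind == "logistic":
            er = np.exp(self.entropy) * raw
            return er / (1.0 + er)
        raise ValueError(f"unknown output kind {kind!r}")

    @property
    def k_params(self) -> int:
        """Number of non-zero coefficients (the AICc parameter count)."""
        return int(np.count_nonzero(self.lam))

    # -- serialisation ------------------------------------------------------
    def to_json(self) -> str:
        spec = self.feature_spec
        doc = {
            "classes": spec.classes,
            "covariates": list(spec.covariates),
            "mins": list(spec.mins),
            "maxs": list(spec.maxs),
            "knots": spec.knots,
            "lam": self.lam.tolist(),
            "rm": self.rm,
            "beta": self.beta.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "converged": self.converged,
            "kkt_residual": self.kkt_residual,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        doc = json.loads(text)
        spec = FeatureSpec(classes=doc["classes"],
                           covariates=tuple(doc["covariates"]),
                           mins=tuple(doc["mins"]), maxs=tuple(doc["maxs"]),
                           knots=doc["knots"])
        return cls(feature_spec=spec, lam=np.array(doc["lam"]), rm=doc["rm"],
                   beta=np.array(doc["beta"]), log_z=doc["log_z"],
                   entropy=doc["entropy"], n_presence=doc["n_presence"],
                   converged=doc["converged"], kkt_residual=doc["kkt_residual"])


def _logsumexp_rows(eta: np.ndarray) -> float:
    m = eta.max()
    return float(m + np.log(np.exp(eta - m).sum()))


def _softmax(eta: np.ndarray) -> np.ndarray:
    e = np.exp(eta - eta.max())
    return e / e.sum()


def _kkt_residual(grad: np.ndarray, lam: np.ndarray, beta: np.ndarray) -> float:
    """Max violation of the subgradient optimality conditions."""
    active = lam != 0
    res_inactive = np.maximum(0.0, np.abs(grad[~active]) - beta[~active])
    res_active = np.abs(grad[active] + np.sign(lam[active]) * beta[active])
    parts = [res_inactive, res_active]
    return float(max((p.max() for p in parts if p.size), default=0.0))


def fit_maxent(presence_features: np.ndarray, background_features: np.ndarray,
               feature_spec: FeatureSpec, rm: float = 1.0,
               max_iter: int = 500, tol: float = 1e-5,
               include_presences: bool = True) -> MaxEntModel:
    """Fit the L1-penalised Gibbs density by accelerated proximal gradient.

    ``presence_features`` (m x p) and ``background_features`` (n x p) are
    expanded feature matrices on a shared :class:`FeatureSpec`.  By
    default the presences are appended to the normalisation background
    (the standard presence-background construction); pass
    ``include_presences=False`` to normalise over the background only.
    """
    if rm <= 0:
        raise ValueError("regularisation multiplier must be positive")
    fp = np.asarray(presence_features, dtype=float)
    fb = np.asarray(background_features, dtype=float)
    if np.isnan(fp).any() or np.isnan(fb).any():
        raise ValueError("NaN in feature matrices")
    m = fp.shape[0]
    if m < 1:
        raise ValueError("need at least one presence")
    norm_bg = np.vstack([fb, fp]) if include_presences else fb

    classes = feature_spec.feature_classes()
    s = norm_bg.std(axis=0)
    beta0 = np.array([_beta0(c, m) for c in classes])
    beta = rm * beta0 * s / np.sqrt(m)
    dead = s == 0  # constant features cannot be matched; freeze at zero
    beta = np.where(dead, np.inf, np.maximum(beta, 1e-12))

    target = fp.mean(axis=0)  # empirical presence feature means

    def grad_smooth(lam: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        eta = norm_bg @ lam
        w = _softmax(eta)
        g = norm_bg.T @ w - target
        val = _logsumexp_rows(eta) - float(fp.mean(axis=0) @ lam)
        return g, val, w

    def prox(v: np.ndarray, step: np.ndarray) -> np.ndarray:
        out = np.sign(v) * np.maximum(0.0, np.abs(v) - step)
        out[dead] = 0.0
        return out

    p = norm_bg.shape[1]
    beta_eff = np.where(dead, 0.0, beta)
    lam = np.zeros(p)
    y = lam.copy()
    t_mom = 1.0
    step = 1.0
    g_y, f_y, _ = grad_smooth(y)
    kkt = _kkt_residual(g_y, lam, np.where(dead, np.abs(g_y) + 1.0, beta))
    converged = kkt <= tol
    it = 0
    while not converged and it < max_iter:
        it += 1
        # backtracking line search on the smooth part
        while True:
            cand = prox(y - step * g_y, step * beta_eff)
            diff = cand - y
            g_cand, f_cand, _ = grad_smooth(cand)
            quad = f_y + float(g_y @ diff) + float(diff @ diff) / (2 * step)
            if f_cand <= quad + 1e-12 or step < 1e-12:
                break
            step *= 0.5
        lam_new = cand
        # gradient-scheme adaptive restart (O'Donoghue & Candes)
        if float((y - lam_new) @ (lam_new - lam)) > 0:
            t_mom = 1.0
            y = lam_new.copy()
        else:
            t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
            y = lam_new + ((t_mom - 1.0) / t_new) * (lam_new - lam)
            t_mom = t_new
        lam = lam_new
        if np.array_equal(y, lam):
            g_y, f_y, _ = grad_smooth(y)
            g_l = g_y
        else:
            g_y, f_y, _ = grad_smooth(y)
            g_l = g_cand
        kkt = _kkt_residual(g_l, lam, np.where(dead, np.abs(g_l) + 1.0, beta))
        converged = kkt <= tol
        step = min(step * 1.5, 1e6)

    if not converged:
        warnings.warn(f"maxent did not converge: KKT residual {kkt:.3g} after {it} iters")

    eta = norm_bg @ lam
    log_z = _logsumexp_rows(eta)
    q = _softmax(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(-(q[q > 0] * np.log(q[q > 0])).sum())
    return MaxEntModel(feature_spec=feature_spec, lam=lam, rm=rm,
                       beta=np.where(dead, np.nan, beta), log_z=log_z,
                       entropy=entropy, n_presence=m, converged=converged,
                       kkt_residual=kkt)


def predict_table(model: MaxEntModel, table: pd.DataFrame, clamp: bool = True,
                  output: str = "cloglog") -> np.ndarray:
    """Suitability scores for a covariate table."""
    features = expand_features(table, model.feature_spec, clamp=clamp)
    return model.output(features, kind=output)


def predict(model: MaxEntModel, stack: ClimateStack, mask: Mask,
            clamp: bool = True, output: str = "cloglog") -> Layer:
    """Project the model onto a climate stack; NaN outside the mask."""
    missing = [c for c in model.feature_spec.covariates if c not in stack]
    if missing:
        raise KeyError(f"stack lacks model covariates {missing}")
    if not stack.grid.conformal_with(mask.grid):
        raise GridConformanceError("stack and mask are not conformal")
    rows, cols = np.nonzero(mask.values)
    table = pd.DataFrame({c: stack[c].values[rows, cols]
                          for c in model.feature_spec.covariates})
    valid = ~table.isna().any(axis=1).to_numpy()
    scores = np.full(len(table), np.nan)
    if valid.any():
        scores[valid] = predict_table(model, table[valid], clamp=clamp, output=output)
    values = np.full(stack.grid.shape, np.nan)
    values[rows, cols] = scores
    return Layer(stack.grid, values, name="suitability")


@dataclass
class BinarizationResult:
    threshold: float
    mask: Mask
    q: float


def binarize(presence_scores, suitability: Layer, q: float = 0.05) -> BinarizationResult:
    """Binary habitat mask at the lower q-percentile of presence scores.

    The threshold is the empirical q-quantile (inverted-CDF convention)
    of the suitability predicted at presence cells; the mask keeps cells
    with suitability >= threshold, so at most a fraction q of the
    presences fall outside.
    """
    thr = lower_quantile(presence_scores, q)
    vals = suitability.values
    mask = Mask(suitability.grid, np.isfinite(vals) & (vals >= thr))
    return BinarizationResult(threshold=thr, mask=mask, q=q)
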