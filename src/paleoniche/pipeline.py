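"""End-to-end orchestration: synthetic world -> niche model -> population.

The :class:`PipelineConfig` captures every tunable (thresholds, feature
grid, folds, seeds); :func:`run_full` executes the chain in memory and
returns all intermediate products, while the stage functions in
:mod:`paleoniche.cli` persist artifacts between subcommands.

Stage order: generate (or load) per-slice climate stacks -> aggregate
intervals -> covariate preselection (correlation + VIF) -> buffered
occurrence sample + shared background -> candidate grid (feature sets x
regularisation multipliers) scored by AICc / OR.10 / AUC -> selected
model projected per interval -> suitability binarised at the 5%-lower
presence percentile -> Miami NPP -> hunter lower/upper density maps ->
P = D-bar x A per interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import covariates as covsel
from . import evaluation, foragers, maxent, occurrence, population
from .climate import TimeInterval, aggregate_interval, miami_npp
from .synthetic import EthnoSimSpec, WorldSpec, build_world, gen_ethno_table

__all__ = ["PipelineConfig", "run_full"]


@dataclass
class PipelineConfig:
    seed: int = 0
    # covariate selection
    r_threshold: float = 0.9
    vif_threshold: float = 5.0
    corr_sample_n: int = 10_000
    priority: tuple = covsel.DEFAULT_PRIORITY
    # occurrence
    buffer_radius_km: float = 10.0
    n_background: int = 10_000
    k_folds: int = 5
    # model grid
    feature_sets: tuple = maxent.FEATURE_CLASS_SETS
    rms: tuple = maxent.REGULARIZATION_MULTIPLIERS
    knots: int = 50
    max_iter: int = 500
    tol: float = 1e-5
    selection_rule: str = "compromise"
    delta_aicc_cap: float = 2000.0
    # binarisation / evaluation
    suitability_percentile: float = 0.05
    # population
    density_strategy: str = "hunters"
    band_size: float = 25.0

    def validate(self) -> None:
        if not (0 < self.suitability_percentile < 1):
            raise ValueError("suitability_percentile must be in (0, 1)")
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must be in (0, 1]")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.band_size <= 0:
            raise ValueError("band_size must be positive")
        if any(rm <= 0 for rm in self.rms):
            raise ValueError("regularisation multipliers must be positive")


def run_full(world_spec: WorldSpec | None = None,
             ethno_spec: EthnoSimSpec | None = None,
             config: PipelineConfig | None = None) -> dict:
    """Run the whole chain on a synthetic world; returns all products.

    Result keys: world, selection, sample, background, folds, metrics,
    chosen, model, suitability, habitat, threshold, npp, fits,
    density_lower/upper, estimates, series, summary, validation_fraction.
    """
    config = config or PipelineConfig()
    config.validate()
    world_spec = world_spec or WorldSpec(seed=config.seed)
    ethno_spec = ethno_spec or EthnoSimSpec()

    world = build_world(world_spec)
    stacks, masks = world["stacks"], world["masks"]
    interval_stacks, interval_masks = world["interval_stacks"], world["interval_masks"]
    sites = world["sites"]

    # --- covariate preselection over pooled onshore slices ---------------
    table = covsel.sample_covariate_table(stacks, masks, n=config.corr_sample_n,
                                          seed=config.seed + 11)
    selection = covsel.select_covariates(table, config.priority,
                                         config.r_threshold, config.vif_threshold)
    retained = selection.retained

    # --- occurrence sample (per interval, pooled) ------------------------
    training, validation = occurrence.multi_occupation_expand(sites)
    samples = []
    for iv_id, stack in interval_stacks.items():
        sub = training[training["interval"] == iv_id]
        if sub.empty:
            continue
        s = occurrence.buffer_sample(sub, stack.subset(retained),
                                     interval_masks[iv_id],
                                     radius_km=config.buffer_radius_km)
        s["interval"] = iv_id
        samples.append(s)
    sample = pd.concat(samples, ignore_index=True)
    folds = occurrence.grouped_kfold(sample, k=config.k_folds,
                                     seed=config.seed + 23)

    # pooled background: climates averaged over all slices, common onshore mask
    mask_all = None
    for m in interval_masks.values():
        mask_all = m if mask_all is None else (mask_all & m)
    pooled_stack = aggregate_interval(
        stacks, TimeInterval("pooled", tuple(stacks), 1.0)).subset(retained)
    n_bg = min(config.n_background, mask_all.n_true)
    background = occurrence.sample_background(mask_all, pooled_stack,
                                              n=n_bg, seed=config.seed + 31)

    # --- candidate grid and model choice ---------------------------------
    metrics, models = evaluation.run_candidate_grid(
        sample, background, retained, folds,
        feature_sets=config.feature_sets, rms=config.rms,
        knots=config.knots, max_iter=config.max_iter, tol=config.tol)
    chosen = evaluation.select_model(metrics, rule=config.selection_rule,
                                     delta_aicc_cap=config.delta_aicc_cap)
    model = models[(chosen["classes"], chosen["rm"])]

    # --- projection, binarisation ----------------------------------------
    suitability = {}
    presence_scores = maxent.predict_table(model, sample[list(model.feature_spec.covariates)])
    habitat = {}
    threshold = None
    for iv_id, stack in interval_stacks.items():
        layer = maxent.predict(model, stack, interval_masks[iv_id])
        suitability[iv_id] = layer
        result = maxent.binarize(presence_scores, layer,
                                 q=config.suitability_percentile)
        habitat[iv_id] = result.mask
        threshold = result.threshold

    # --- external validation on undated assemblages ----------------------
    validation_fraction, validation_report = evaluation.external_validation(
        habitat, validation)

    # --- forager regressions ---------------------------------------------
    ethno_raw = gen_ethno_table(ethno_spec, seed=config.seed + 41)
    prepared = foragers.prepare_ethno(ethno_raw)
    prepared["strategy"] = foragers.classify_strategy(prepared,
                                                      seed=config.seed + 43)
    fits = foragers.fit_strategy_table(prepared)

    strat = config.density_strategy
    env = {kind: foragers.RegressionFit(
        intercept=float(row["intercept"]), slope=float(row["slope"]),
        r=float(row["r"]), p=float(row["p"]), n=int(row["n"]))
        for kind, row in (
            (k, fits[(fits["strategy"] == strat) & (fits["kind"] == k)].iloc[0])
            for k in ("lower", "upper"))}

    # --- NPP, density, population ----------------------------------------
    npp_layers, density_lower, density_upper = {}, {}, {}
    est_lower, est_upper = [], []
    for iv_id, stack in interval_stacks.items():
        npp = miami_npp(stack["BIO1"], stack["BIO12"])
        npp_layers[iv_id] = npp
        d_lo = population.density_map(npp, env["lower"], habitat[iv_id], "lower")
        d_hi = population.density_map(npp, env["upper"], habitat[iv_id], "upper")
        density_lower[iv_id], density_upper[iv_id] = d_lo, d_hi
        est_lower.append(population.total_population(d_lo, habitat[iv_id],
                                                     interval_id=iv_id))
        est_upper.append(population.total_population(d_hi, habitat[iv_id],
                                                     interval_id=iv_id))
    series, summary = population.interval_series(est_lower, est_upper)
    summary["bands_min"] = population.band_count(summary["p_min"], config.band_size)
    summary["bands_max"] = population.band_count(summary["p_max"], config.band_size)

    return {
        "config": config,
        "world": world,
        "selection": selection,
        "sample": sample,
        "background": background,
        "folds": folds,
        "metrics": metrics,
        "chosen": chosen,
        "model": model,
        "suitability": suitability,
        "habitat": habitat,
        "threshold": threshold,
        "presence_scores": presence_scores,
        "validation_fraction": validation_fraction,
        "validation_report": validation_report,
        "ethno": prepared,
        "fits": fits,
        "npp": npp_layers,
        "density_lower": density_lower,
        "density_upper": density_upper,
        "estimates_lower": est_lower,
        "estimates_upper": est_upper,
        "series": series,
        "summary": summary,
    }
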