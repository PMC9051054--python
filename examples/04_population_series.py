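"""Sustainable population per interval: P = D-bar x A.

Projects the fitted niche model onto each glacial/interglacial interval,
converts the interval climate to Miami-model NPP, applies the hunter
lower/upper density equations inside the suitable area, and integrates
to a total sustainable population.
"""

from paleoniche import PipelineConfig, WorldSpec, run_full
from paleoniche.population import band_count

cfg = PipelineConfig(seed=5, n_background=2000, corr_sample_n=4000,
                     feature_sets=("L", "LQ", "LQP"), rms=(0.4, 1.0),
                     knots=10, k_folds=4, max_iter=300, tol=1e-4)
res = run_full(WorldSpec(seed=5, n_rows=100, n_cols=100), config=cfg)

cols = ["interval", "area_km2", "mean_density_lower", "p_lower", "p_upper"]
print(res["series"][cols].round(1).to_string(index=False))

s = res["summary"]
print(f"\nmaximum population: {s['p_max']:,.0f} in {s['max_interval']} "
      f"(interglacial); minimum {s['p_min']:,.0f} in {s['min_interval']} "
      f"(glacial) -- a {s['percent_drop']:.0f}% drop driven by the "
      f"shrinking suitable area, not by density (mean density stays "
      f"nearly constant).")
print(f"at 25 individuals per band: {band_count(s['p_min'])} bands in the "
      f"coldest interval, {band_count(s['p_max'])} in the warmest")
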