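"""Balanced resampling and the five diet-seasonality indicators.

Draws 100 balanced subsamples (4 herds per species-season), computes
turnover, richness, total niche width and the two uniqueness indices per
replicate, and fits the allometric models on the replicate means.
"""

from dietshift import (
    CommunityConfig,
    SubsampleDesign,
    ancova_type3,
    generate_diet_table,
    run_indicators,
    turnover_allometry,
)

cfg = CommunityConfig(seed=1)
table, _ = generate_diet_table(cfg)
ind = run_indicators(table, SubsampleDesign(n_per_cell=4, n_reps=100, seed=2))

print("replicate means per species-season:")
print(ind.replicate_means().round(2), "\n")

fit = turnover_allometry(ind, cfg.species_masses)
print(
    f"turnover ~ log10 mass(g): slope = {fit.slope:.4f}, "
    f"R^2 = {fit.r2:.3f}, p = {fit.p:.4f}"
)
print("(a negative slope: larger species switch diets less between seasons)\n")

for resp in ("herd_richness", "TNW_at_8", "herd_dprime", "species_dprime"):
    a = ancova_type3(ind, resp, cfg.species_masses)
    kept = "interaction kept" if "*" in a.final_model else a.final_model
    print(f"{resp:<15} -> {kept}")
print(
    "\nEach indicator keeps the simplest model the likelihood-ratio chain"
    " cannot reject: mass and season effects for richness and niche width,"
    " and a mass x season interaction for the uniqueness indices (larger"
    " species become more unique in winter). Exact choices can vary"
    " slightly between simulated datasets."
)
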