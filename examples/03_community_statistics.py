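"""Permutation statistics on the diet dissimilarity matrix.

perMANOVA partitions Bray-Curtis dissimilarity by species, season and
their interaction; the dispersion test compares between-herd variance
across seasons; NMDS embeds the samples for plotting.
"""

from dietshift import (
    CommunityConfig,
    bray_curtis,
    dispersion,
    generate_diet_table,
    nmds,
    permanova,
    permutest,
)

table, _ = generate_diet_table(CommunityConfig(seed=1))
D = bray_curtis(table.counts.values, labels=table.sample_ids)

res = permanova(D, table.sample_meta[["species", "season"]], n_perm=999, seed=3)
print("perMANOVA (999 permutations):")
print(res.table.round(3), "\n")

disp = dispersion(D, table.sample_meta["season"].values)
p = permutest(disp, n_perm=999, seed=4)
print("between-herd dispersion (distance to seasonal spatial median):")
print(disp.group_means.round(3))
print(f"permutation p = {p:.3f}\n")

emb = nmds(D, k=2, n_restarts=4, seed=5)
print(f"NMDS stress = {emb.stress:.3f} ({'converged' if emb.converged else 'not converged'})")
print("low stress means the 2-D map preserves the dissimilarity ranks well")
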