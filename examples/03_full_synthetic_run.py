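"""A full seasonal analysis of one synthetic dataset.

Simulates the combined scenario (limiting similarity + phylogenetically
clustered dry-season loss) at study size — 12 stream sites, a 31-species
pool, wet richness 5-15, dry richness 2-12 — and runs the whole pipeline:
Gower/UPGMA functional diversity, Faith phylogenetic diversity, a
1000-replicate turnover-preserving null ensemble, paired observed-vs-null
tests, redundancy regressions and Moran's I.
"""

import divnull as dn

ds = dn.simulate_dataset(dn.ScenarioConfig(scenario="CD"), seed=42)
report, bundle = dn.analyze(
    ds.occurrences,
    ds.traits,
    ds.tree,
    coords=ds.coordinates,
    replicates=1000,
    seed=42,
)

print("Global paired tests (positive mean difference = observed above null):")
print(report.global_tests.round(4).to_string(index=False), end="\n\n")

dry = report.regressions.query("season == 'dry' and response == 'FD_observed'")
print("Dry-season FD ~ SR model selection:")
print(dry[["selected", "quadratic_coef", "r_squared"]].round(4).to_string(index=False), end="\n\n")

print("Moran's I spatial autocorrelation (diversity should be uncorrelated")
print("with site position in this simulation):")
print(report.morans.round(4).to_string(index=False), end="\n\n")

print(
    "Expected signature under this scenario: the dry-season FD test has a\n"
    "POSITIVE mean difference (assemblages functionally overdispersed) while\n"
    "the dry-season PD test is NEGATIVE (phylogenetically clustered), both\n"
    "with small p — richness alone cannot produce this, because the null\n"
    "matches observed richness exactly."
)
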