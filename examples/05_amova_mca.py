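"""Hierarchical AMOVA and multiple correspondence analysis of synthetic data.

Simulates two groups of two populations with deep between-group divergence,
partitions the molecular variance, then runs an MCA on planted SNP states
with the population of origin as a supplementary variable.
"""

from ylineage import (
    GenealogySpec,
    STRModel,
    amova_two_level,
    build_structured_genealogy,
    default_tree,
    mca,
    place_snps_on_genealogy,
    simulate_structured_populations,
)

spec = GenealogySpec(
    "two_level_hierarchy", n_samples=80, age_generations=100.0,
    group_sizes=[[20, 20], [20, 20]], divergence_generations=(55.0, 25.0),
    seed=6,
)
profiles = simulate_structured_populations(spec, STRModel(mu_per_locus_per_gen=3e-3))

res = amova_two_level(profiles, n_permutations=999, seed=6)
print("AMOVA (pairwise-difference distance, 999 permutations):")
for level in res.levels:
    print(f"  {level.source:32s} df={level.df:3d}  V={level.variance:8.4f}  {level.percent:7.2f}%")
print(f"  percentages sum to {res.percent_total():.2f}")
for name, p in res.p_values.items():
    print(f"  {name}: {res.phi[name]:.4f} (p={p:.3f})")

genealogy = build_structured_genealogy(spec)
pinned = {
    "Q-L56": "root", "Q-M346": "root", "Q-L54": "root",
    "Q-M3": "root", "Q-M848": "root",
    "Q-CO24/CO27": "G1", "Q-CO15": "G1P1", "Q-CO22": "G1P2",
    "Q-SA05": "G2", "Q-Z5915": "G2P1",
}
placement = place_snps_on_genealogy(
    genealogy, default_tree(), seed=6, branch_of_node=pinned
)
mca_res = mca(placement.table, supplementary="population")
print("\nMCA of SNP states (origin supplementary):")
print(f"  dims 1-2 explain {mca_res.cumulative_percent_dims12:.2f}% of total inertia")
print("  supplementary origin coordinates (dim1):")
for cat, row in mca_res.supp_coords.iterrows():
    print(f"    {cat:24s} {row['dim1']:+.3f}")
# Deep shared group drift shows up as a large among-group variance
# component; populations of the same group co-locate on the MCA axes.
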