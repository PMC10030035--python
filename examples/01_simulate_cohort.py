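"""Generate a synthetic many-trait mapping cohort with known pleiotropy.

Builds a small structured panel (3 subpopulations, LD blocks, four trait
categories) in which 10% of genic intervals carry a causal site shared by
four traits, and prints what the generator planted.
"""

from pleioscan import SimConfig, simulate_cohort

cfg = SimConfig(
    n_samples=300, n_chrom=3, sites_per_chrom=600, ld_block_len=15,
    within_block_r=0.6, n_subpops=3, fst_like_divergence=0.15,
    genes_per_chrom=20,
    traits_per_category={"nam_field": 10, "gap_field": 10,
                         "mass_feature": 10, "expression": 12},
    pleiotropy_rate=0.10, traits_per_pleiotropic_site=4, h2=0.7, seed=1,
)
cohort = simulate_cohort(cfg)

G = cohort.genotypes
print(f"genotypes: {G.n_samples} samples x {G.n_sites} sites, "
      f"MAF range {G.maf().min():.3f}-{G.maf().max():.3f}")
print(f"intervals: {len(cohort.intervals.df)} "
      f"({len(cohort.intervals.genic())} genic)")
print(f"traits: {cohort.traits.values.shape[1]} across 4 categories")
print(f"planted pleiotropic intervals: {len(cohort.truth.pleiotropic_intervals)}")
for site, iid in sorted(cohort.truth.shared_sites.items()):
    traits = [t for t, _ in cohort.truth.causal_map[site]]
    print(f"  shared site {site} in {iid}: affects {len(traits)} traits "
          f"({traits[0]}, {traits[1]}, ...)")
# Each listed interval hosts one causal site whose effect is shared across
# several same-category traits — the ground truth the pipeline should flag.
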