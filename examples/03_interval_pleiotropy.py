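"""Interval pleiotropy scores from observed vs permuted scans.

Runs the scan on observed traits and on residual-permuted replicates,
counts unique traits per genic/intergenic interval, and scores enrichment
as ln((obs+1)/(perm_mean+1)) with the five-fold flag.
"""

from pleioscan import (SimConfig, compute_global_pcs, fast_association,
                       maf_filter, permute_phenotypes, score_table,
                       simulate_cohort, summarize_category)
from pleioscan.intervals import assign_hits, build_count_table

cohort = simulate_cohort(SimConfig(
    n_samples=350, n_chrom=3, sites_per_chrom=700, n_subpops=2,
    fst_like_divergence=0.1, genes_per_chrom=25,
    traits_per_category={"nam_field": 20, "gap_field": 1,
                         "mass_feature": 1, "expression": 1},
    pleiotropy_rate=0.12, traits_per_pleiotropic_site=5, h2=0.7, seed=3))

G = maf_filter(cohort.genotypes)
pcs = compute_global_pcs(G, G, k=3)
T = cohort.traits.subset(cohort.traits.category_traits("nam_field"))

reps = {"observed": assign_hits(
    fast_association(T, G, pcs).df, cohort.intervals)}
for i, Tp in enumerate(permute_phenotypes(T, pcs, n_perm=10, seed=3), 1):
    reps[f"perm_{i}"] = assign_hits(fast_association(Tp, G, pcs).df,
                                    cohort.intervals)

counts = build_count_table(reps, list(cohort.intervals.ids))
scores = score_table(counts, unit_types=cohort.intervals.types())
summary = summarize_category(scores, "nam_field", n_traits=20)

print(f"{summary.pct_flagged:.2f}% of {summary.n_units} intervals are "
      "five-fold enriched over their permutation null")
print(f"flagged intervals carry {summary.flagged_min:.0f}-"
      f"{summary.flagged_max:.0f} traits (median {summary.flagged_median:.0f})")
print(f"{summary.pct_units_le1:.1f}% of intervals map 0-1 traits "
      "(the L-shaped bulk of the distribution)")
flagged = set(scores.index[scores["five_fold"]])
truth = cohort.truth.pleiotropic_intervals
print(f"flags recover {len(flagged & truth)}/{len(truth)} planted intervals")
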