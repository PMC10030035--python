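# Methods

`pleioscan` quantifies *statistical pleiotropy* — the tendency of a genomic
region to associate with many traits — from many-trait GWAS summary results,
and then asks how much of that signal is explained by mapping resolution
rather than biology. This note documents the model, the parameters that
matter, what the synthetic cohort generator does and does not emulate, and
the numerical choices made where the design was open.

## The pleiotropy statistic

The genome is partitioned into alternating genic and intergenic intervals:
overlapping or abutting gene ranges are merged into single genic intervals
and the per-chromosome complement forms the intergenic ones, so interval
lengths sum exactly to chromosome lengths and genic/intergenic counts differ
by at most one per chromosome. Every significant trait–SNP association
(p < 1e-5 after covariate adjustment) is assigned to the interval containing
its position, and the pleiotropy of an interval is the number of *distinct*
traits hitting it — a trait associating through twenty SNPs of one LD block
counts once.

The null is built by residual permutation: each trait is regressed on its
mapping covariates, the residuals are shuffled (independently per trait and
replicate), and the fitted values are added back, so the permuted trait keeps
the structure the mapping model controls for while trait–genotype and
trait–trait covariances are broken. Genotypes are never permuted, preserving
LD. Field and mass-feature traits use 10 permutation replicates, expression
traits 5. For the two-model window-PC category each replicate is permuted
under each scan model's own covariates (shared shuffle indices): permuting
under the union of both models' covariates leaves a genotype-aligned fitted
component in the scan that omits part of the union and measurably inflates
null hit counts.

Per interval the enrichment statistic is

    E = ln((obs + 1) / (perm_mean + 1)),

with a pseudo-count of one in numerator and denominator so intervals with
zero counts stay defined. An interval is **five-fold enriched** when
(obs + 1) >= 5 (perm_mean + 1), i.e. E >= ln 5. The raw ratio is also
reported, but the pseudo-counted ratio carries the flag, consistent with
the statistic that is plotted. The same machinery runs at SNP level on a
uniform without-replacement subsample of sites.

## Association scan

The scan is a fixed-effects "fast association": traits and genotype dosages
are residualized once against the covariate design (intercept + covariates,
orthonormalized by SVD), and every trait x site statistic comes from a single
cross-product. For residualized vectors, t = r sqrt(df / (1 - r^2)) with
df = n - rank(C) - 1 and two-sided p from the t distribution (not a normal
approximation — at a few hundred samples the difference matters in the far
tail). This is numerically identical to per-pair OLS of
trait ~ intercept + covariates + genotype; the test suite asserts agreement
to 1e-8 relative tolerance. Sites with MAF < 0.01 are removed beforehand
("minimum allele frequency" is read as the smallest allowed value, so a site
at exactly 0.01 is kept); sites constant after residualization are skipped.

Covariates come in three families:

* **global PCs** (default k = 3) of a reference genotype panel, target
  samples projected onto the reference axes; PC signs are fixed by making
  the largest-magnitude loading positive.
* **gene-window PCs** for structured multi-family panels: genes are ordered
  per chromosome, grouped into windows of `window_genes` genes, and a
  "mid" set shifted by half a window absorbs edge effects. Per window the
  smallest number of PCs whose cumulative explained-variance share reaches
  `var_target` (default 0.15) is kept; total variance is the sum of that
  window's eigenvalues. A SNP belongs to the window whose genomic span
  (first gene start to last gene end, half-open) contains it; SNPs outside
  all spans attach to the nearest window; windows with fewer than two SNPs
  contribute nothing. Windows never span a chromosome boundary. The scan
  runs once per window set (main, mid) and hits are unioned per (trait,
  site), keeping the smaller p-value.
* **hidden factors** for expression traits: truncated-SVD factor scores of
  the column-standardized trait residuals (after removing global PCs).
  These play the role latent-factor methods (PEER-style) play for real
  expression data — an internal, deterministic stand-in with the same
  interface.

The defaults `window_genes=20, shift_genes=10` in `RunConfig` are scaled to
the synthetic genome (tens of genes per chromosome); on a real annotation
the field-standard values are 360/180, which are the defaults of
`compute_window_pcs` itself.

## Nuisance adjustment

Raw unique-trait counts confound biology with mapping artifacts: intervals
with more scanned SNPs, longer spans, or higher internal LD accumulate more
hits regardless of causal sharing. Four models quantify this:

| model | estimator | features |
|---|---|---|
| 1 | random forest, 500 trees, impurity importance | mean pairwise LD r², number of input SNPs, interval size |
| 2 | random forest | model 1 + mean conservation over hit sites, peak count, max RNA/protein expression, interval type, adjusted expression pleiotropy |
| 3 | random forest | model 2 + 14 GO indicator columns |
| 4 | gradient boosting, eta 0.5, depth 6, 100 rounds | model 2's features |

All models are evaluated leave-one-chromosome-out; per-fold R² is the
squared Pearson correlation of held-out predictions vs observations, and
per-fold seeds are `master + fold_index`. **Adjusted pleiotropy** is the
observed count minus the *held-out* Model-1 prediction — held-out rather
than refit-on-all, so the adjustment can never memorize the unit it adjusts.
Missing features (LD for one-SNP intervals, conservation for hitless
intervals, expression for intergenic ones) are median-imputed with a
missingness indicator column; tree models split on the indicator freely.
The number of boosting rounds is fixed at 100 with no early stopping, for
determinism. Expression pleiotropy is adjusted first and its adjusted score
feeds the other categories' models, reflecting expression's position
upstream in the central dogma.

When observed counts are substantially predictable from the nuisance
features (held-out Model-1 R² above ~0.75), the adjusted score decorrelates
from the observed one (|r| < 0.5). When planted biological sharing dominates
— which the nuisance model cannot and should not predict — the adjusted
score necessarily tracks the observed count; this is the intended behaviour,
not a failure of the adjustment.

## GO enrichment

Adjusted scores of genic intervals are cut at the 75th/90th/99th percentile
(high sets) and 25th/10th/1st (low sets), linear interpolation, ties at the
cut included. Genes of the selected intervals are tested per GO term with a
one-sided (enrichment) Fisher exact test against the universe of all
GO-annotated genes in scored genic intervals, and Benjamini–Hochberg FDR is
applied within each ontology separately; q < 0.05 is reported, capped at the
13 smallest q per ontology in the report view. Annotations are used as
given — no propagation up the GO graph (a known limitation relative to
graph-aware testers, whose elim/weight decorrelation is also out of scope).

## The synthetic cohort generator

The generator provides the study conditions every test runs under; its
defaults are fixed and are not tuned per test.

**Genotypes.** Sites come in LD blocks. Each block draws one allele
frequency (uniform 0.1–0.5; per subpopulation it is redrawn from a
Balding–Nichols Beta distribution with divergence `fst_like_divergence`).
Within a block, each haplotype's per-site uniform copies a per-sample block
anchor with probability sqrt(`within_block_r`), otherwise it is fresh; the
allele is the indicator that the uniform falls below the block frequency.
With a shared block frequency this one-factor copula gives pairwise dosage
correlation exactly `within_block_r`, hence mean within-block r² equal to
`within_block_r`² — a direct dial for the LD the interval statistic must
cope with. (A latent-Gaussian threshold construction was evaluated and
rejected: discretizing to dosage levels attenuates the correlation well
below its nominal value, making the dial dishonest.) `within_block_r=0`
reduces to independent sites, `=1` to identical sites.

**Traits.** Four categories mirror a two-panel maize study: structured-panel
field traits (mapped with global + window PCs under the two-model union),
diversity-panel field traits and mass features (global PCs only), and
expression traits (global PCs + hidden factors). Each trait is a sum of
standardized-genotype effects at its private causal sites (Gaussian
effects), scaled to variance `h2`, plus Gaussian noise of variance 1 − `h2`.
A fraction `pleiotropy_rate` of genic intervals receives one shared causal
site affecting `traits_per_pleiotropic_site` traits of a single category
(categories rotate across planted intervals), with one effect-magnitude
draw per site and independent signs per trait unless the concordant flag is
set. Optional subpopulation mean shifts on a random subset of traits
(`structure_confound_sd`) emulate residual-structure inflation; hidden
factors load only on expression traits.

**Annotations.** Conservation scores per site, chromatin peaks, per-gene
expression maxima and a gene→GO map are generated with a per-track coupling
dial in [0, 1]: at 0 each track is independent of true pleiotropy by
construction; at 1 pleiotropic intervals get deterministically shifted
conservation/expression, extra peaks, and a dedicated GO term on their
genes.

**What it does not emulate.** Realistic demography, recombination maps and
gene-density variation, imputation error, trait-measurement structure
(replicates, environments), GO-graph topology, genome scale. Sites are
uniformly spaced with uniform density, so the nuisance features
(n_input_snps, interval_size) vary only through interval-length variation —
weaker nuisance gradients than a real genome. Consequently a passing
recovery test shows the machinery is correct and calibrated on a known
truth, not that real-data effect sizes or the real balance between artifact
and biology are reproduced.

**Determinism.** All randomness flows from one master seed through named
substreams (genotypes / genes / traits / annotations / permutations / LOCO
folds), so a fixed seed reproduces every artifact byte-for-byte.

## Reference study conditions and problem sizes

Two conditions anchor the calibration and recovery tests and the
acceptance script, chosen as the package's standard demonstration sizes:

* **null** — 300 samples, 5 chromosomes × 1,000 sites, 60 pure-noise traits
  (no causal sites, one subpopulation), 10 permutations (5 for expression).
  Expected behaviour: total hit counts within binomial bounds of
  sites × traits × 1e-5 (a factor ≤ 2 for the two-model union), five-fold
  flagged fraction ≤ 2%.
* **recovery** — 400 samples, 5 × 1,500 sites, 105 traits across the four
  categories, 5% of genic intervals planted with 5-trait shared sites at
  h2 = 0.6. Expected behaviour: five-fold flags enriched for the planted
  intervals (Fisher p < 0.01) and higher adjusted pleiotropy there
  (one-sided Mann–Whitney p < 0.01).

A third, artifact-driven condition (8 subpopulations controlled by only 3
global PCs, structure-confounded traits) reproduces the qualitative
signatures of spurious pleiotropy: observed hits far exceeding the
permutation null, and more five-fold flags in the longer intergenic
intervals than in genic ones.

## Numerical choices and degenerate inputs

* p-values from the t distribution; residualization via an SVD-derived
  orthonormal basis; |r| clipped to 1 before the t transform.
* MAF boundary kept at ≥ threshold (tolerance 1e-12); the five-fold flag
  uses ≥ with the same tolerance.
* Percentiles: linear interpolation; ties included on both sides; an
  all-equal adjusted-score vector makes high = low = all and is logged as
  degenerate.
* Medians over flagged counts use standard interpolation for even counts.
* Empty categories, empty hit stores, hitless intervals, one-SNP intervals
  and geneless chromosomes are all defined states, not errors; genuinely
  inconsistent inputs (genes beyond chromosome ends, hits outside the
  tiling, rank-deficient permutation designs, LOCO with one chromosome)
  raise.
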