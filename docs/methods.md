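# Methods

This note documents the models and procedures implemented in `tme_profiler`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohort does and does not establish.

## Cohort data model

All artifacts are UTF-8 TSV with header rows. Expression is a genes ×
samples matrix in TPM (transcripts per million); gene symbols are matched
case-sensitively after whitespace trimming, with no alias resolution (alias
maps are version-dependent and would make results irreproducible across
annotation releases). Duplicate gene rows collapse to the per-cell maximum
TPM with a logged warning — deterministic and conservative for signature
scoring, since a signature gene can only score from its strongest probe.
Missing optional manifest fields are encoded as empty strings.

## Composite signature scores

All composite scores are built from per-gene z-scores taken **across the
whole cohort**, not within groups: the non-functional CD8 rule compares
*FGFBP2* against the whole-cohort median, which fixes the reference
population. z-scores use the population SD (divide by n), configurable to
the sample SD via `ddof=1`. Expression is transformed to log2(TPM+1) before
standardization by default (`transform="none"` is available and makes the
scores invariant to per-gene rescaling).

- **IFNγ score**: mean of per-gene z over the signature genes present.
  The mean (rather than sum) keeps the score comparable when some signature
  genes are missing from a matrix; the fraction present is logged and zero
  present is an error. Gene membership ships as an editable GMT
  (`data/immune_signatures.gmt`), defaulting to the published 6-gene
  interferon-gamma and 18-gene expanded T cell-inflamed response signatures;
  these memberships come from the cited signature publications, not from
  any single cohort study, and are meant to be replaced freely.
- **T cell dysfunction score**: z(*HAVCR2*) + z(*LAG3*) + z(*PDCD1*), a sum
  by definition.
- **STING score**: sum of z over *TMEM173*, *CGAS*, *CCL5*, *CXCL10*,
  *IRF3*, mirroring the dysfunction score's sum construction; a mean variant
  is available (`aggregation="mean_z"`).
- **T cell-inflamed classification**: score below `t_low` → TIS−, above
  `t_high` → TIS+, otherwise undetermined, with both comparisons strict so
  ties fall into "undetermined". Published three-way thresholds are not
  available, so the defaults are the cohort tertiles of the score; with
  distinct scores this partitions any cohort into classes whose sizes differ
  by at most one. Thresholds are overridable.
- **Non-functional CD8 rule**: dysfunction strictly > 1.0 **and** *FGFBP2*
  strictly below the cohort median, evaluated only among samples with
  non-zero deconvolved CD8 fraction; zero-CD8 samples are recorded missing
  so they drop out of any percentage denominator. Both inequalities are
  strict, following the bracketed definitions ("> 1.0", "less than the
  median").

## Immune deconvolution

Bulk expression is modeled as a non-negative combination of cell-type
reference profiles over marker genes. Per sample: the mixture is
re-normalized to the TPM scale (1e6 over all genes), restricted to the
signature's marker genes, and fitted by non-negative least squares
(`scipy.optimize.nnls`); the weights, divided by per-type mRNA-content
scales, are the absolute fractions; `other = max(0, 1 − Σw)` absorbs
tumor/stromal signal; rows are renormalized to sum to 1.

Choices and caveats:

- The per-type mRNA-content scales of the published absolute-fraction
  method are not reproducible from its description, so they default to 1
  and are configurable. With unit scales the estimator preserves the
  ranking/correlation structure used downstream; absolute levels shift if
  cell types differ substantially in mRNA content.
- TPM renormalization of the mixture makes the estimate invariant to any
  positive rescaling of a sample. It assumes the mixture and the reference
  share (approximately) the same gene universe; the packaged default
  reference is the synthetic generator's TPM-normalized profile matrix, and
  a user-supplied matrix is a drop-in TSV in the same layout.
- Marker genes missing from the mixture are dropped from both sides
  (zero-filling would bias weights toward zero); at least 50% of markers
  must be present.
- "Other" is a single remainder; tumor and stroma are not distinguished.

On noiseless synthetic mixtures the estimator recovers the planted
fractions to < 1e-6 (machine precision in practice); recovery error
increases monotonically with expression noise.

## Enrichment

**Enrichment score.** For a ranked list of N genes and a set of size k,
hits increment the running sum by |metric|^α / Σ_set |metric|^α and misses
decrement by 1/(N−k); the ES is the signed maximum deviation. Ties in the
ranking metric are broken by gene symbol for determinism; ties in |running
sum| resolve to the earliest position. At α = 0 the ES depends only on
ranks and lies in [−1, 1].

**Preranked GSEA.** The null is built by gene-label permutation preserving
set size (the pipeline consumes precomputed contrasts, so phenotype
permutation is not applicable). NES = ES / mean(|null ES| of matching
sign). The p-value is the +1-smoothed empirical tail probability on the
null tail matching the observed sign — enrichment is detected in either
direction, and under the null the p-values are approximately uniform
(verified by a pooled Kolmogorov bound in the test suite). Two FDR columns
are reported: Benjamini–Hochberg over the empirical p-values (`fdr`, the
default, simpler and conservative) and the classic sign-stratified
NES-ratio estimate (`fdr_nes`).

**ssGSEA.** Per sample, genes are ordered by expression (descending, gene
symbol tie-break) and the score is the summed difference between the
rank-weighted hit ECDF (weights = rank position^α, α = 0.25 by default per
the method's convention) and the unweighted miss ECDF over all positions.
Because the weights are rank positions, scores depend only on the ordering,
so any per-sample monotone rescaling of expression leaves them unchanged.
Sets with no gene present score missing with a warning. The normalized
variant divides the whole score matrix by its (max − min) range.

## Genomic features

- **Pathogenicity filter**: exactly {pathogenic, likely_pathogenic} are
  counted as mutations; VUS, likely benign, and benign are excluded. The
  filter is idempotent.
- **TMB**: count of missense variants not flagged germline, divided by the
  sequencing footprint (default 1.4 MB, the 592-gene panel); TMB-high at
  ≥ 10 mut/MB with the boundary classified high. "Non-synonymous missense"
  is interpreted literally (nonsense/frameshift excluded); a broader
  qualifying set can be configured by the caller filtering records first.
- **Mutation frequency**: distinct mutated samples over assessed samples in
  the group, with an explicit optional assessed-samples list per gene
  (sequencing coverage differs per gene in real panels, so denominators can
  be smaller than the group; coverage is an explicit input, never imputed).
  Percentages round half-up to one decimal, matching conventional
  reporting.
- **HLA homozygosity**: allele1 == allele2 (string equality after
  whitespace normalization) at each of the seven loci (HLA-A/B/C,
  HLA-DPA1/DPB1/DQB1/DRB1); samples missing a locus leave that locus's
  denominator. Parental homozygosity and LOH are not distinguishable from
  genotypes alone and are not disambiguated.
- **Neoantigen bins**: the published interval descriptions leave exactly
  50, 500, and 5000 nmol/L unassigned; lower-closed half-open intervals
  [0,50), [50,500), [500,5000), [5000,∞) are used as a documented
  convention. Bin counts per sample always sum to the record count.

## Statistics

Kruskal–Wallis (tie-corrected, via scipy) with Benjamini–Hochberg
adjustment across exactly the variable family passed in one call — families
from different analyses are never pooled, matching per-analysis correction.
When every observation in a variable is identical the test is reported as
H = 0, p = 1 (scipy's tie correction would otherwise return NaN).
Mann–Whitney is exact for combined n ≤ 20 without ties and uses the normal
approximation with tie/continuity correction otherwise. Proportion tests
use Fisher's exact test on 2×2 tables whenever any expected cell is ≤ 5
(the boundary is included so that balanced degenerate tables are handled
exactly) and chi-square otherwise. Correlation matrices use
pairwise-complete observations, record pairs with < 4 complete observations
as missing, and carry a mask marking non-significant entries (p > α).

Differential expression: log2fc = log2(mean_A + c) − log2(mean_B + c) on
TPM with pseudocount c = 1; the per-gene test defaults to Mann–Whitney for
consistency with the rest of the comparison layer (Welch's t on log2(TPM+1)
is available); BH across all genes; the significance threshold α is a
parameter defaulting to 0.05; pass `alpha=0.01` for a stricter call set.

## Synthetic cohort generator

The generator is the test bed: it emulates the statistical structure the
analysis assumes, with every planted effect recoverable from the returned
`SyntheticTruth`.

- **Reference profiles**: log-normal background expression (median ~50,
  log-SD 1) with each cell type's disjoint block of 20 marker genes boosted
  by 3 log2 units; columns TPM-normalized. Ten immune types plus tumor.
- **Mixing**: per-sample fractions from group-specific Dirichlet priors;
  the tumor fraction is floored at 0.3 (microdissected specimens carry
  substantial tumor content) by rescaling the immune components.
- **Expression**: convex mixture of profiles × 2^(group shifts) ×
  2^(σ·N(0,1)) multiplicative log-normal noise (σ = 0.25 by default, a
  typical bulk RNA-seq log-scale dispersion), then re-TPM-normalized.
- **Planted shifts** (log2, MBM unless noted): IFNγ −1.0, TIS −1.0,
  STING −0.7, *TNF* −1.0, *IL12B* −1.0, dysfunction +0.5, OXPHOS +1.0,
  TCA +0.8, GLYC +0.4, plus +0.8 on angiogenesis genes and *VEGFA*/*STAT3*
  in PTEN-mutant MBM samples. Cohort studies report directions and
  significance for these contrasts, not effect sizes, so the magnitudes are
  free parameters of the generator chosen once to give clearly detectable
  effects at the default cohort size; they are configuration, not
  estimates.
- **Mutations**: driver genes (BRAF/NRAS/NF1/PTEN) Bernoulli per group at
  rates reported for real-world melanoma cohorts (PTEN 8.1/16.3/6.0% in
  PCM/MBM/ECM, BRAF ~0.48-0.50, NRAS 0.22-0.25, NF1 0.15); total missense
  burden negative-binomial with group means 9/14/9 mut/MB × 1.4 MB and
  dispersion r = 3; extra germline-flagged and synonymous records exercise
  the filters.
- **HLA / neoantigens**: per-locus homozygosity probability 0.15 at all
  seven loci in all groups (no group difference, as observed); neoantigen
  counts Poisson-linked to the mutation burden (so load correlates with
  TMB); IC50 log10-uniform over [0.5, 4.5], covering all four bins.
- **Seeding**: one master seed spawns independent child streams per table
  (fractions, noise, mutations, HLA, neoantigens, manifest), so adding a
  table never perturbs existing ones and outputs are byte-identical across
  runs.

What the generator does **not** emulate: read-level sampling, gene–gene
correlation beyond cell-type mixing, eQTL-style mutation–expression
linkage (the PTEN→angiogenesis shift is the one deliberate exception),
matched multi-site samples, batch effects, or within-group heterogeneity of
effect sizes. Passing tests therefore establish that the estimators recover
what was planted under this variance model — not that real cohorts satisfy
the model.

## Problem sizes and reproducibility

The default synthetic cohort matches the real cohort's sizes (350 PCM +
94 MBM + 870 ECM = 1,314 samples) over a 1,000-gene universe; power and
recovery properties use reduced universes (330 genes, the minimum carrying
all marker blocks and named signature genes) and n = 50/group over 100
seeds. `scripts/acceptance.py --seed N --out results/acceptance.json`
derives every random stream from the given seed and reruns the whole set of
checks from scratch; the pipeline's run manifest (seed, config hash,
package versions) suffices to reproduce a report bit-identically.

## Known limitations

- Deconvolution accuracy degrades when mixture and reference gene universes
  diverge or when mRNA-content scales differ across cell types (defaults
  assume unit scales).
- The preranked GSEA gene-permutation null ignores inter-gene correlation;
  p-values are calibrated for exchangeable metrics only.
- The TIS tertile default makes the classification cohort-relative; fixed
  thresholds must be supplied to compare classifications across cohorts.
- Percentage rounding (half-up, one decimal) is applied at the reporting
  boundary only; all internal computations are full precision.
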