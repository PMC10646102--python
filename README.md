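# tme-profiler

Immunogenomic profiling of the melanoma tumor microenvironment across three
anatomic cohorts: primary cutaneous melanoma (PCM), melanoma brain metastases
(MBM), and extracranial metastases (ECM). The package implements, as one
tested pipeline, the transcriptomic and genomic analyses used to
characterize why brain metastases present a colder, metabolically distinct
microenvironment:

- **Composite expression signatures** on cohort z-scores of log2(TPM+1):
  an interferon-gamma (IFNγ) response score (mean of per-gene z), a three-way
  T cell-inflamed classification (TIS+ / undetermined / TIS−, default
  thresholds at cohort tertiles), a T cell dysfunction score
  (z(*HAVCR2*) + z(*LAG3*) + z(*PDCD1*)), a STING-pathway score
  (sum of z over *TMEM173*, *CGAS*, *CCL5*, *CXCL10*, *IRF3*), and the
  non-functional CD8 rule (dysfunction > 1.0 and *FGFBP2* below the cohort
  median, among samples with non-zero CD8 infiltration).
- **Immune deconvolution**: absolute fractions of ten immune cell types by
  non-negative least squares of the TPM-normalized mixture on a marker-gene
  reference matrix, with a non-negative "other" remainder,
  `min_w ||S w − m||²  s.t.  w ≥ 0`.
- **Enrichment**: preranked GSEA (weighted Kolmogorov–Smirnov running sum,
  gene-permutation null, NES, empirical p, BH and NES-ratio FDR) and
  per-sample ssGSEA (rank-weighted hit/miss ECDF difference, exponent 0.25).
- **Genomic features**: tumor mutational burden (non-synonymous missense,
  non-germline, per 1.4 MB; TMB-high at ≥ 10 mut/MB), pathogenic /
  likely-pathogenic mutation frequencies with per-gene assessed denominators,
  HLA homozygosity at seven loci, and neoantigen IC50 affinity bins at
  50 / 500 / 5000 nmol/L.
- **Statistics**: Kruskal–Wallis with Benjamini–Hochberg correction,
  exact/asymptotic Mann–Whitney, Fisher/chi-square proportion tests,
  Spearman correlation matrices with significance masks, and log2
  fold-change differential expression.

Because the original patient-level data are proprietary, the package ships a
first-class synthetic cohort generator (`tme_profiler.synthetic`) that
plants the cohort's statistical structure — group sizes 350/94/870, mixing
fractions from group-specific Dirichlet priors, log-normal expression noise,
group-level log2 shifts on the signature gene families, driver-gene mutation
probabilities, negative-binomial mutation burdens, HLA homozygosity rates,
and log-uniform IC50 values — so every downstream stage is testable end to
end with known ground truth.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic cohort:

```bash
python analysis/01_simulate_cohort.py --seed 0      # writes results/cohort/
python analysis/02_signature_scores.py
python analysis/03_immune_deconvolution.py
python analysis/04_genomic_features.py
python analysis/05_enrichment_analysis.py
python analysis/06_full_report.py --seed 0          # the whole pipeline in one pass
```

Output from this exact sequence (seed 0):

```
median IFNg score: PCM=0.258, MBM=-2.705, ECM=0.199
TIS(+) percentage: PCM=40.0%, MBM=0.0%, ECM=34.3%
ifng_score: KW H=268.53, adjusted p=1.46e-58
...
deconvolved 1314 samples into 10 immune cell types + other
  B cells: lower in MBM (median 0.0627 vs PCM 0.0903, adj p=2.1e-11)
  Tregs: lower in MBM (median 0.0533 vs PCM 0.0711, adj p=1.3e-07)
...
TMB-high percentage: PCM=40.0%, MBM=62.8%, ECM=36.9%
pathogenic PTEN mutation rate: PCM=10.0%, MBM=20.2%, ECM=5.4%
GSEA OXPHOS: NES=5.27, p=0.00221, FDR=0.00295
MBM: angiogenesis ssGSEA PTEN-mut vs wt, median 196.6 vs -30.6, p=2.03e-11
```

Read: the brain-metastasis group scores lower on the IFNγ signature and has
no TIS+ tumors, fewer inferred B cells and Tregs, a higher TMB-high rate and
pathogenic *PTEN* mutation rate, enrichment of oxidative phosphorylation in
the MBM-vs-PCM contrast, and angiogenesis enrichment specifically in
*PTEN*-mutant MBM — exactly the effects planted by the generator, recovered
by the analysis stages.

The same pipeline runs from the shell over user-supplied TSV/GMT inputs:

```bash
tme-profiler run --config config.yaml --out results/report --seed 0
tme-profiler score --expr expr.tsv --manifest manifest.tsv --out scores.tsv
tme-profiler deconvolve --expr expr.tsv --signature sig.tsv --out fractions.tsv
```

## Layout

```
src/tme_profiler/   library: cohort_io, synthetic, signatures, deconv,
                    enrichment, genomics, stats, pipeline, cli, datasets
analysis/           numbered narrative drivers over the library
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance.py
docs/methods.md     models, parameters, numerical choices, limitations
```
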