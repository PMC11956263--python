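# ataqtl

Chromatin-accessibility QTL (caQTL) mapping from ATAC-seq samples that come
**without genotypes**. ATAC-seq reads carry sequence at nucleotide
resolution, so donor genotypes can be inferred directly from the reads that
pile up in accessible chromatin; with genotypes in hand, duplicate samples
of one donor can be recognized and merged, accessibility peaks called
jointly across samples, variants tested for association with peak
accessibility, and the resulting caQTL signals linked to eQTL/GWAS signals
by Bayesian colocalization.

`ataqtl` implements that whole chain as a tested library plus a thin CLI,
together with a synthetic-data generator that produces every input with
known ground truth, so the pipeline's accuracy claims are measurable.

## What is inside

| module | contents |
|---|---|
| `ataqtl.synthdata` | haplotype reference panel with LD (copying-mosaic process), diploid donor cohorts, sparse peak-concentrated read pileups, negative-binomial peak counts with planted genotype effects, paired association summary statistics |
| `ataqtl.genotype` | binomial genotype likelihoods; diploid Li–Stephens imputation (forward–backward over ordered haplotype pairs, O(n²) per site via the rank-one transition); direct calls; a learned direct/imputed combiner; effective coverage; concordance metrics |
| `ataqtl.donorid` | AF-centered Spearman correlation of called genotypes between samples; donor = connected component above a threshold; per-donor phenotype aggregation |
| `ataqtl.peakcall` | per-sample Poisson bin p-values → Fisher's method across samples → BH + merge into peaks; quantification, outlier-peak filters, CPM normalization |
| `ataqtl.qtlmap` | cis-window scans (MAF > 0.05, ±10 kb), covariate-adjusted OLS, Freedman–Lane permutation peak-level p-values (optional beta approximation), Storey q-values, precision/recall benchmarking |
| `ataqtl.colocal` | Wakefield ABFs, single-causal-variant colocalization posteriors PP0–PP4, the PP3+PP4 / PP4-ratio decision rule, GWAS lead clumping |
| `ataqtl.repstats` | π1 replication (λ-grid median), AF/TSS-matched background variants, fold enrichment with permutation p, blacklist-aware interval shuffling, annotation labeling |
| `ataqtl.clusterctx` | 2-D embedding + k-means context clusters, per-cluster peak filters, within-cluster caQTL remapping, cross-cluster π1 matrix |
| `ataqtl.pipeline` / `ataqtl.cli` | end-to-end orchestration with manifests, artifact validation, `ataqtl` console command |

## The statistics at the core

**Genotype inference.** At a panel site with `r` reference and `a` alternate
reads and error rate ε, the likelihood of `g ∈ {0,1,2}` alternate alleles is
`C(d,a)·p_g^a·(1−p_g)^(d−a)` with `p_0 = ε, p_1 = ½, p_2 = 1−ε`. These
triplets are the emissions of a diploid Li–Stephens HMM whose hidden state
is an ordered pair of panel haplotypes: each haplotype independently
switches template with probability `s` per site and mis-copies its template
allele with probability `μ_c`. Posterior dosage `E[g | reads, panel]` at
every panel site comes from the forward–backward algorithm; the factorized
transition makes each step O(n_hap²).

**caQTL mapping.** For peak `p` with donor-level phenotype
`y = log2(CPM+1)`, every biallelic variant with MAF > 0.05 within 10 kb of
the peak boundaries is tested by OLS of `y` on dosage plus genotype PCs and
phenotype PCs. The peak-level p-value is calibrated by permuting the
covariate-residualized phenotype (Freedman–Lane, with re-projection of the
permuted residuals): `p_emp = (1 + #{perm min-p ≤ observed}) / (B + 1)`.
Storey q-values with `π0 = median over λ ∈ {0.1,…,0.9}` of
`#{p>λ}/((1−λ)m)` control the FDR across peaks.

**Colocalization.** Per variant, `log ABF = ½·log(V/(V+W)) + ½·z²·W/(V+W)`
(`V = se²`, `W` prior effect variance). Hypothesis sums over single-causal
configurations give PP0–PP4; a locus is colocalized when `PP3+PP4 > 0.8`
and `PP4/(PP3+PP4) > 0.9`.

## Worked example

Run the whole pipeline on the default simulated cohort (40 donors
contributing 1–2 samples each, 150 peaks, 1,500 panel sites):

```bash
ataqtl run-all --seed 7 --outdir demo
```

which prints

```json
{
  "caqtl_n_inferred": 25,
  "caqtl_n_truth": 26,
  "caqtl_precision": 1.0,
  "caqtl_recall": 0.9615384615384616,
  "lead_causal_overlap": 27,
  "lead_causal_p": 0.009900990099009901,
  "median_spearman": 0.9159820411952386,
  "n_clusters": 3,
  "n_donors": 40,
  "n_peaks_called": 150
}
```

Reading the numbers: the median Spearman correlation between genotypes
imputed from the sparse reads and the true donor genotypes is **0.92**; all
**40** true donors were recovered from sample-genotype correlations; all
**150** planted accessibility peaks were re-called from the binned
coverage; of the 26 peaks that carry a significant caQTL when the true
genotypes are used, **25** are also found with the read-inferred genotypes
(recall 0.96) with no extra false calls (precision 1.0); and **27** of the
significant lead variants coincide with a planted causal variant, far more
than AF-matched background draws (permutation p ≈ 0.0099). `demo/` holds the
panel and genotype VCFs, peak BEDs, count matrices, per-sample concordance,
caQTL tables, cluster assignments, the enrichment report, colocalization
scenario results, and a `manifest.json` with seeds and a parameter hash;
rerunning with the same seed reproduces every file byte-for-byte.

Each stage is equally usable as a library; see the module docstrings for
`simulate_panel → simulate_cohort → simulate_reads`,
`pileup_likelihoods → impute`, `map_caqtls`, `coloc_posteriors`, etc.

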