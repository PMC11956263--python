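# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of `ataqtl`. Nothing here states a result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Genotype model

Reads are reduced to per-site reference/alternate counts. Likelihoods are
binomial with alt-read probabilities ε, ½, 1−ε for 0/1/2 alt alleles; a
site with no reads carries the flat triplet (1,1,1) — absence of reads is
absence of evidence, never certainty. A uniform genotype prior is used
inside the likelihoods so that panel information enters *only* through the
imputation HMM; this keeps the two evidence sources separable for the
direct/imputed combiner.

Imputation is a diploid Li–Stephens copying model. The hidden state at site
*m* is an ordered pair of panel haplotypes; per site each haplotype
independently switches to a uniformly chosen template with probability
`switch_rate` (so the single-haplotype transition is
`(1−s)·I + (s/n)·J`, and the pair transition factorizes into two rank-one
updates, O(n_hap²) per site instead of O(n_hap⁴)). The state emits a true
genotype — each copied allele mismatching its template with probability
`copy_error` — which is scored against the site's likelihood triplet.
Forward variables are renormalized at every site (underflow-safe); the
forward pass is stored (float64 up to ~256 MB, float32 beyond) and the
backward pass accumulates per-site posterior genotype probabilities by
combining the pre-emission forward state, the backward state, and the
rank-structured emission decomposition. Correctness is pinned by an
exhaustive path-enumeration oracle on 4-haplotype/3-site instances
(|Δ| < 1e−10).

Parameters and defaults: `switch_rate = 0.002`/site and
`copy_error = 0.01` match the generator's mosaic rates, i.e. the HMM is run
at the generating process's own parameters; `eps = 0.01` per read. A
`min_depth = 2` rule governs direct calls (fewer than two reads is treated
as missing). The combiner is a logistic regression on
(log depth, direct-call margin, imputed-posterior margin, agreement flag)
trained on an 80/20 sample split at sites where direct and imputed hard
calls disagree; with degenerate training data it falls back to a
deterministic rule (trust the direct call iff depth ≥ 8). The main
pipeline reports the pure likelihood+imputation genotypes; the combiner is
exercised by its own tests.

## Donor deduplication

Samples of one donor share a genotype. The pairwise statistic is the
Spearman correlation of **AF-centered posterior dosages** over sites
non-missing in both samples. Centering (by twice the cohort or panel
allele frequency) matters: raw genotypes of unrelated individuals
correlate substantially through shared allele frequencies alone, which
would bury the identity signal. Continuous dosages are used rather than
hard calls because for two samples of one donor the panel-shrinkage
component at sparsely covered sites is *shared* signal. Donors are the
connected components of the graph with edges at correlation ≥ τ = 0.8;
transitive closure is deliberate (a low-coverage sample may link to its
donor through any one sibling). Labels are the lexicographically smallest
member id, so output is deterministic. A multi-sample donor's genotype is
taken from its highest-effective-coverage sample rather than re-estimated
jointly — the simplest reproducible rule.

At effective coverage near the 0.1 boundary the weakest same-donor pairs
can fall just below τ (observed once across six probed seeds in the
recovery suite's conditions); above ~0.15 coverage recovery is exact in
every run we compute. τ trades missed merges against false merges; the
unrelated-pair distribution sits near 0 with an upper tail around 0.3–0.4
under the default generator, so τ = 0.8 has a wide safe margin on that
side.

## Peak calling

Per sample, per 50-bp bin (configurable), the p-value is the upper-tail
Poisson probability of the observed read count under a per-sample
background rate (total reads × bin/chromosome length unless supplied).
Fisher's method combines the per-sample p-values per bin
(X = −2Σln p ~ χ²_{2k}); Benjamini–Hochberg q-values are computed over
bins, and bins with q ≤ 0.05 outside the blacklist are merged into peaks
when gaps are ≤ 100 bp. The Poisson null is a deliberately simple stand-in
with the same per-sample-then-Fisher aggregation structure as
ATAC-optimized joint callers; it is not a fragment-level model. Counts are
CPM-normalized against the in-peak library size (the column sum), which is
computable from the count matrix alone. Outlier-peak filters: mean count
< 1, max count > 100,000, or zero counts in more than ~48.6% of samples.

## caQTL mapping

Phenotype: donor-level mean CPM per peak, transformed as log2(CPM+1)
(rank-inverse-normal available). Covariates: 3 genotype PCs plus phenotype
PCs; the phenotype-PC count scales as min(0.15·n_donors, 200) because a
fixed large count does not transfer to small cohorts; an elbow-scan helper
(`choose_phenotype_pcs`) is provided for data-driven selection on a peak
subset. PCA uses a fixed sign convention (largest-magnitude loading
positive) for determinism.

Per peak, variants with MAF > 0.05 (strict) within
[start − 10 kb, end + 10 kb) are tested by OLS via the Frisch–Waugh
projection; the per-variant t-test equals the full normal-equation fit to
1e−8 (oracle-tested). The peak-level statistic is the minimum nominal p
(equivalently the maximum absolute partial correlation). Permutations are
Freedman–Lane: the covariate-residualized phenotype is permuted **and
re-residualized against the covariate basis** before correlating — without
the re-projection the permuted vectors regain a component in the covariate
span, permutation correlations shrink by ≈ √(1−k/n), and the test is
anti-conservative (we measured 9.4% of null peaks below p = 0.05 with 15
phenotype PCs at n = 100; after the fix the null is uniform, KS p ≈ 0.46).
`p_emp = (1+#{perm ≤ obs})/(B+1)` with B = 1,000 by default; a
moment-matched beta approximation to the permutation null is available for
continuous p-values below the 1/(B+1) floor but the direct estimator is
the reference. Lead-variant ties break to the smallest genomic position.
Storey q-values use the λ-grid {0.1, 0.15, …, 0.9} with the median-π0
estimator clamped to (0,1]; forcing π0 = 1 reproduces BH exactly
(oracle-tested against statsmodels).

The precision/recall benchmark declares significance by BH-corrected
peak-level p < 0.05 in each analysis separately and intersects the
significant peak sets: precision = |inferred ∩ truth|/|inferred|,
recall = |truth ∩ inferred|/|truth|.

## Colocalization

Wakefield log-ABFs with prior effect sd 0.15 (quantitative) / 0.2
(case-control); priors p1 = p2 = 1e−4, p12 = 1e−5, the long-standing
defaults of the standard colocalization software, adopted unchanged.
Single-causal-variant enumeration per locus; all sums in log
space, with H3 computed as log(e^{s1+s2} − e^{s12}) so a one-variant locus
yields PP3 = 0 exactly. Decision rule: PP3+PP4 > 0.8 (power) and
PP4/(PP3+PP4) > 0.9 (specificity); an undefined ratio fails. GWAS lead
selection: iteratively take the most significant variant with p ≤ 5e−8,
clump everything within ±50 kb at r² > 0.01 (dosage Pearson on the
analysis cohort).

## Replication and enrichment statistics

π1 = 1 − median over the λ grid of π0(λ), with π0 clamped to [0,1] before
the median (the raw estimator exceeds 1 at small m). Matched backgrounds
sample, per lead and iteration, one non-lead pool variant with allele
frequency within ±10% and |TSS distance| within ±10% (relative tolerances
by default; absolute mode available — the phrasing "± 10%" is ambiguous
and we chose relative). Enrichment p-values use the +1/(n+1) correction so
p = 0 is impossible. Interval shuffling preserves length and chromosome
and rejects blacklist overlaps (≤ 1,000 tries per interval, then a named
error).

## Context clusters

The reference 2-D embedding is PCA of feature-standardized log2(CPM+1) —
deterministic and sufficient for the stated contract (well-separated
groups stay separated; planted-group silhouette > 0.5); any 2-D embedder
honoring the contract can be substituted. k-means (10 restarts, fixed
seed) with silhouette-based selection over a k grid; samples beyond the
99.5th percentile of centroid distance are flagged outliers and excluded
from memberships. Per cluster, peaks must have non-zero signal in ≥ 50% of
the cluster's samples (inclusive) to be remapped; cross-cluster
replication is the π1 of one cluster's significant peaks evaluated on
another cluster's empirical p-values, diagonal excluded.

## The synthetic-data generator

The generator *defines* the study conditions; it emulates:

* a phased biallelic panel whose LD comes from a copying-mosaic process —
  `max(2, n_hap/4)` i.i.d. Bernoulli(½) founders, every later haplotype a
  mosaic of earlier ones (switch 0.002/site, mutation 0.01/site). Founder
  diversity is essential: with very few founders the panel is a single
  pedigree and even unrelated donors share most alleles identically by
  descent, erasing the bimodal donor-correlation structure;
* diploid donors as two mosaic recombinants of panel haplotypes, each
  donor contributing 1–`dup_k_max` samples;
* reads only at panel sites: depth ~ Poisson(3/site inside peaks,
  0.02 outside), each read reporting a uniformly chosen haplotype's allele
  flipped with probability 0.01 — no fragment model, no indels, since
  genotyping consumes only site pileups;
* peak counts ~ negative binomial (dispersion α = 0.1, variance μ+αμ²)
  with mean μ_p·exp(g·β) at causal peaks, g the donor's causal-variant
  dosage shared by all its samples; baselines log-normal around 100;
* summary statistics with marginal effects propagated through cohort LD
  (β_v = β_c·cov(g_v,g_c)/var(g_v)), SE = 1/√(2·n·AF·(1−AF)), under
  shared / distinct (r² < 0.2) / one-null causal scenarios.

One master seed derives independent per-stage streams by stable name
hashing, so outputs are byte-identical under a fixed seed and adding a
stage never perturbs another. What the generator does *not* model — and
hence what green tests do not establish about real data: fragment-length
and Tn5 insertion structure, duplicate-read artifacts, reference bias,
copy-number variation, indels/multiallelics, population admixture beyond
the founder mosaic, batch effects across studies.

## Benchmark problem sizes

The benchmark suites run at desk scale, chosen once: genotype concordance
on a 200-haplotype, 2,000-site panel with 30 single-sample donors at
effective coverage ≈ 0.3 (peaks covering ~31% of a 2-Mb chromosome);
dual-genotype caQTL benchmarking with 60 donors, 500 peaks (100 planted
caQTLs, log effects 0.4–0.8, 2 in-peak sites per peak plus uniform
background sites, 3-Mb chromosome, 100-haplotype panel), with the 100-kb
variant placing causal variants up to 80 kb away from any covered peak;
FDR control with 100 donors, 2,000 peaks, 20% planted effects (log 0.6,
B = 200) averaged over 5 derived seeds. The end-to-end demo uses 40 donors,
150 peaks, 1,500 sites.

## Known limitations

* The Poisson bin null is a stand-in for a fragment-aware joint peak
  caller; absolute peak boundaries are bin-quantized.
* Permutation p-values are exchangeability-based; donor relatedness beyond
  the genotype PCs is not modeled.
* The combiner's feature set is fixed and small; it arbitrates hard-call
  disagreements and is not a general genotype refiner.
* Single-causal-variant colocalization only; loci with multiple causal
  variants per trait violate the model's assumption.
* Near effective coverage 0.1 the donor-merge threshold can miss a
  weakly-covered sample (see above); in that regime a lower τ or deeper
  sequencing of flagged singletons is advisable.
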