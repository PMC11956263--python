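"""End-to-end orchestration: simulate -> genotype -> donors -> peaks -> caQTL -> coloc.

Each stage reads and writes plain-text artifacts (VCF/BED/TSV) in the output
directory and records them in a JSON manifest together with the seeds and a
parameter hash, so a run is reproducible and resumable from disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .colocal import coloc_decision, coloc_posteriors
from .donorid import aggregate_by_donor, assign_donors, pairwise_dosage_correlation
from .genotype import (
    DosageMatrix,
    ImputationParams,
    effective_coverage,
    genotype_concordance,
    impute,
    pileup_likelihoods,
)
from .peakcall import call_peaks, cpm_normalize, filter_peaks, fisher_combine, per_sample_bin_pvalues
from .qtlmap import QtlConfig, benchmark_precision_recall, map_caqtls
from .synthdata import (
    SimConfig,
    plant_caqtl_effects,
    simulate_bin_coverage,
    simulate_cohort,
    simulate_panel,
    simulate_peaks,
    simulate_reads,
    simulate_summary_stats,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_io"]


@dataclass
class PipelineConfig:
    """Nested configuration for a full pipeline run.

    The default demo scale (40 donors, 150 peaks, 1,500 sites, 60 panel
    haplotypes) keeps a full run to a couple of minutes on one CPU while
    still exercising every stage.
    """

    sim: SimConfig = field(
        default_factory=lambda: SimConfig(
            n_hap=60, n_sites=1500, n_donors=40, dup_k_max=2, n_peaks=150, chrom_length=1_500_000
        )
    )
    qtl: QtlConfig = field(default_factory=lambda: QtlConfig(n_permutations=200))
    imputation: ImputationParams = field(default_factory=ImputationParams)
    donor_tau: float = 0.8
    stages: tuple[str, ...] = (
        "simulate", "genotype", "donors", "peaks", "qtl", "cluster", "enrich", "coloc"
    )
    outdir: str = "ataqtl_run"
    seed: int = 0

    def param_hash(self) -> str:
        payload = json.dumps(
            {
                "sim": asdict(self.sim),
                "qtl": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in asdict(self.qtl).items()},
                "imputation": asdict(self.imputation),
                "donor_tau": self.donor_tau,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.sim.seed = cfg.seed
    cfg.qtl.seed = cfg.seed
    manifest: dict = {"seed": cfg.seed, "param_hash": cfg.param_hash(), "outputs": {}, "metrics": {}}

    peaks = simulate_peaks(cfg.sim)
    panel = simulate_panel(cfg.sim, peaks)
    truth = simulate_cohort(panel, cfg.sim)
    truth = plant_caqtl_effects(truth, peaks, panel, cfg.sim)
    pileup, counts = simulate_reads(truth, peaks, cfg.sim, panel)

    if "simulate" in cfg.stages:
        aio.write_panel_vcf(panel, out / "panel.vcf")
        aio.write_bed(peaks, out / "peaks_true.bed")
        aio.write_dosage_vcf(
            truth.dosage_matrix(panel.site_positions), out / "truth_genotypes.vcf",
            chrom=panel.chrom, chrom_length=panel.chrom_length,
        )
        aio.write_matrix_tsv(counts, out / "peak_counts.tsv")
        manifest["outputs"]["simulate"] = ["panel.vcf", "peaks_true.bed", "truth_genotypes.vcf", "peak_counts.tsv"]

    gl = pileup_likelihoods(pileup, cfg.sim.seq_error)
    eff_cov = effective_coverage(pileup, panel)
    imputed = impute(gl, panel, cfg.imputation)
    if "genotype" in cfg.stages:
        aio.write_dosage_vcf(imputed, out / "called_genotypes.vcf", chrom=panel.chrom, chrom_length=panel.chrom_length)
        conc = genotype_concordance(imputed, truth.dosage_matrix(panel.site_positions, per_sample=True))
        conc["effective_coverage"] = eff_cov
        conc.to_csv(out / "genotype_concordance.tsv", sep="\t", index=False)
        manifest["outputs"]["genotype"] = ["called_genotypes.vcf", "genotype_concordance.tsv"]
        manifest["metrics"]["median_spearman"] = float(conc["spearman"].median())

    counts_f = filter_peaks(counts)
    cpm = cpm_normalize(counts_f)

    corr = pairwise_dosage_correlation(imputed)
    assignment = assign_donors(corr, list(pileup.sample_ids), cfg.donor_tau)
    donor_cpm = aggregate_by_donor(cpm, assignment)
    # donor genotype: each donor's highest-effective-coverage sample
    rep_idx = []
    for d in assignment.donor_ids:
        members = assignment.members(d)
        ix = [pileup.sample_ids.index(s) for s in members]
        rep_idx.append(ix[int(np.argmax(eff_cov[ix]))])
    donor_dosage = DosageMatrix(assignment.donor_ids, panel.site_positions, imputed.dosage[rep_idx])
    if "donors" in cfg.stages:
        dmap = assignment.to_dataframe()
        dmap["effective_coverage"] = eff_cov
        dmap.to_csv(out / "donor_map.tsv", sep="\t", index=False)
        pd.DataFrame(corr, index=pileup.sample_ids, columns=pileup.sample_ids).to_csv(
            out / "sample_correlation.tsv", sep="\t", index_label="sample_id"
        )
        manifest["outputs"]["donors"] = ["donor_map.tsv", "sample_correlation.tsv"]
        manifest["metrics"]["n_donors"] = assignment.n_donors

    if "peaks" in cfg.stages:
        cov = simulate_bin_coverage(peaks, cfg.sim, n_samples=min(len(pileup.sample_ids), 20))
        p_bins = per_sample_bin_pvalues(cov, bin_size=50, chrom_length=cfg.sim.chrom_length)
        combined = fisher_combine(p_bins, axis=1)
        called = call_peaks(combined, bin_size=50, chrom=cfg.sim.chrom)
        aio.write_bed(called, out / "peaks_called.bed")
        manifest["outputs"]["peaks"] = ["peaks_called.bed"]
        manifest["metrics"]["n_peaks_called"] = len(called)

    if "qtl" in cfg.stages:
        res_inferred = map_caqtls(donor_cpm, donor_dosage, peaks, cfg.qtl)
        # truth-genotype analysis on the true donor partition for benchmarking
        true_assign_cpm = _truth_donor_cpm(cpm, truth)
        truth_dosage = truth.dosage_matrix(panel.site_positions)
        res_truth = map_caqtls(true_assign_cpm, truth_dosage, peaks, cfg.qtl)
        res_inferred.to_csv(out / "caqtl_inferred.tsv", sep="\t", index=False)
        res_truth.to_csv(out / "caqtl_truth.tsv", sep="\t", index=False)
        bench = benchmark_precision_recall(res_inferred, res_truth, alpha=cfg.qtl.fdr)
        manifest["outputs"]["qtl"] = ["caqtl_inferred.tsv", "caqtl_truth.tsv"]
        manifest["metrics"].update({f"caqtl_{k}": v for k, v in bench.items()})

    if "cluster" in cfg.stages:
        from .clusterctx import embed_samples, kmeans_clusters

        coords = embed_samples(cpm, seed=cfg.seed)
        cassign = kmeans_clusters(coords, k_grid=[2, 3, 4], seed=cfg.seed)
        cassign.sample_ids = list(cpm.sample_ids)
        cassign.to_dataframe().to_csv(out / "clusters.tsv", sep="\t", index=False)
        manifest["outputs"]["cluster"] = ["clusters.tsv"]
        manifest["metrics"]["n_clusters"] = cassign.k

    if "enrich" in cfg.stages and "qtl" in cfg.stages:
        from .repstats import enrichment, matched_background_variants

        sig = res_inferred.loc[res_inferred["significant"].fillna(False)]
        tested = res_inferred["lead_variant"].dropna().astype(int)
        af_all = imputed.af
        lead_ids = set(sig["lead_variant"].astype(int))
        pool_idx = [v for v in tested.unique() if v not in lead_ids]
        causal_set = {f"v{v}" for v, _ in truth.causal_map.values()}
        if lead_ids and pool_idx:
            # the synthetic genome carries no genes, so backgrounds are
            # matched on allele frequency only (TSS distance is vacuous)
            mk = lambda idx: pd.DataFrame(
                {
                    "variant_id": [f"v{v}" for v in idx],
                    "af": [af_all[v] for v in idx],
                    "tss_distance": 0,
                }
            )
            bgs = matched_background_variants(
                mk(sorted(lead_ids)), mk(pool_idx), n_iter=100, seed=cfg.seed
            )
            enr = enrichment({f"v{v}" for v in lead_ids}, bgs, causal_set)
            report = {
                "observed": enr.observed,
                "mean_background": float(enr.background.mean()),
                "fold": None if np.isnan(enr.fold) else enr.fold,
                "p": enr.p,
                "n_iterations": len(bgs),
            }
            with open(out / "enrichment.json", "w") as fh:
                json.dump(report, fh, indent=2)
            manifest["outputs"]["enrich"] = ["enrichment.json"]
            manifest["metrics"]["lead_causal_overlap"] = enr.observed
            manifest["metrics"]["lead_causal_p"] = enr.p

    if "coloc" in cfg.stages:
        rows = []
        for scenario in ("shared", "distinct", "one_null"):
            poly = np.flatnonzero((truth.true_dosages.var(axis=0) > 0))[:40]
            s1, s2 = simulate_summary_stats(
                truth, poly, scenario, n_eff=10_000, cfg=cfg.sim, seed_stage=f"coloc_{scenario}"
            )
            r = coloc_posteriors(s1, s2)
            rows.append(
                {"scenario": scenario, **{f"pp{i}": v for i, v in enumerate(r.pp)}, "decision": coloc_decision(r)}
            )
        pd.DataFrame(rows).to_csv(out / "coloc_scenarios.tsv", sep="\t", index=False)
        manifest["outputs"]["coloc"] = ["coloc_scenarios.tsv"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _truth_donor_cpm(cpm, truth):
    from .donorid import DonorAssignment, aggregate_by_donor

    corr = np.eye(len(truth.sample_ids))
    assign = DonorAssignment(list(truth.sample_ids), dict(truth.sample_to_donor), corr)
    return aggregate_by_donor(cpm, assign)


def validate_io(paths: dict[str, str | Path]) -> list[str]:
    """Structural validation of pipeline artifacts; returns human-readable issues.

    Checks BED interval sanity and sortedness, VCF parseability, and
    sample-id consistency between a genotype VCF and a count-matrix TSV.
    Problems are reported, never silently corrected.
    """
    issues: list[str] = []
    bed = paths.get("bed")
    if bed:
        df = pd.read_csv(bed, sep="\t", header=None, comment="#")
        bad = df[df.iloc[:, 1] >= df.iloc[:, 2]]
        for _, row in bad.iterrows():
            issues.append(f"BED {bed}: start >= end at {row.iloc[0]}:{row.iloc[1]}-{row.iloc[2]}")
        if not df.iloc[:, 1].is_monotonic_increasing:
            issues.append(f"BED {bed}: intervals not sorted by start")
    vcf_path = paths.get("vcf")
    vcf_samples: list[str] | None = None
    if vcf_path:
        try:
            from cyvcf2 import VCF

            vcf = VCF(str(vcf_path))
            vcf_samples = list(vcf.samples)
            last = 0
            for var in vcf:
                if var.POS < 1:
                    issues.append(f"VCF {vcf_path}: non-positive POS {var.POS}")
                if var.POS < last:
                    issues.append(f"VCF {vcf_path}: unsorted at POS {var.POS}")
                last = var.POS
        except Exception as exc:  # malformed file
            issues.append(f"VCF {vcf_path}: unreadable ({exc})")
    matrix = paths.get("matrix")
    if matrix and vcf_samples is not None:
        cols = pd.read_csv(matrix, sep="\t", nrows=0).columns.tolist()
        matrix_samples = [c for c in cols if c != "peak_id"]
        if set(matrix_samples) != set(vcf_samples):
            issues.append(f"sample ids differ between {vcf_path} and {matrix}")
    return issues
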