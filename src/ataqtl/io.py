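"""Plain-text interchange: VCF, BED, and TSV readers/writers.

Coordinate conventions follow the standards: BED is 0-based half-open, VCF
is 1-based.  VCF reading goes through cyvcf2; writing emits minimal VCF
v4.2 text (phased GT for the panel, unphased GT plus DS for called
genotypes).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import DosageMatrix, ReadPileup
from .peakcall import CpmMatrix, PeakCountMatrix, PeakSet
from .synthdata import HaplotypePanel

__all__ = [
    "write_panel_vcf",
    "write_dosage_vcf",
    "read_panel_vcf",
    "read_dosage_vcf",
    "write_bed",
    "read_bed",
    "write_pileup_tsv",
    "read_pileup_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_phenotype_bed",
    "read_phenotype_bed",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
"""


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the phased haplotype panel; haplotype 2h/2h+1 form sample h."""
    n_ind = panel.n_hap // 2
    samples = [f"ref_{i:04d}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=panel.chrom, length=panel.chrom_length))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        H = panel.haplotypes
        for m, pos in enumerate(panel.site_positions):
            gts = "\t".join(f"{H[2 * i, m]}|{H[2 * i + 1, m]}" for i in range(n_ind))
            fh.write(
                f"{panel.chrom}\t{pos + 1}\t{panel.chrom}:{pos + 1}\t"
                f"{panel.ref_allele[m]}\t{panel.alt_allele[m]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dosage_vcf(
    dosages: DosageMatrix, path: str | Path, chrom: str = "chr1", chrom_length: int = 0
) -> None:
    """Write unphased hard calls (GT) and dosages (DS)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(chrom=chrom, length=chrom_length or 2**29))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.sample_ids)
            + "\n"
        )
        hard = dosages.hard_call
        if hard is None:
            with np.errstate(invalid="ignore"):
                hard = np.where(
                    np.isnan(dosages.dosage), -1, np.clip(np.round(dosages.dosage), 0, 2)
                ).astype(np.int8)
        for m, pos in enumerate(dosages.positions):
            cells = []
            for i in range(len(dosages.sample_ids)):
                d = dosages.dosage[i, m]
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    cells.append(f"{gt_map[int(hard[i, m])]}:{d:.4f}")
            fh.write(
                f"{chrom}\t{pos + 1}\t{chrom}:{pos + 1}\tA\tG\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_panel_vcf(path: str | Path) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    positions, haps, refs, alts = [], [], [], []
    chrom = None
    for var in vcf:
        chrom = var.CHROM
        positions.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        row = []
        for g in var.genotypes:  # [a0, a1, phased]
            row.extend([g[0], g[1]])
        haps.append(row)
    length = 0
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig") and f"ID={chrom}" in line:
            length = int(line.split("length=")[1].rstrip(">"))
    H = np.array(haps, dtype=np.int8).T
    return HaplotypePanel(
        chrom, length or (max(positions) + 1), np.array(positions), np.array(refs), np.array(alts), H
    )


def read_dosage_vcf(path: str | Path) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions, dosage_rows, hard_rows = [], [], []
    for var in vcf:
        positions.append(var.POS - 1)
        ds = var.format("DS")
        dosage_rows.append(np.where(np.isnan(ds[:, 0]), np.nan, ds[:, 0]))
        hard = np.array([g[0] + g[1] if g[0] >= 0 else -1 for g in var.genotypes], dtype=np.int8)
        hard_rows.append(hard)
    return DosageMatrix(
        samples,
        np.array(positions),
        np.array(dosage_rows).T,
        np.array(hard_rows).T,
    )


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    """BED6 with name = peak_id and score = -log10 q (capped at 1000)."""
    q = peaks.combined_q if peaks.combined_q is not None else np.ones(len(peaks))
    with open(path, "w") as fh:
        for i in range(len(peaks)):
            score = min(1000, int(round(-10 * np.log10(max(q[i], 1e-100)))))
            fh.write(
                f"{peaks.chrom}\t{peaks.starts[i]}\t{peaks.ends[i]}\t"
                f"{peaks.peak_ids[i]}\t{score}\t.\n"
            )


def read_bed(path: str | Path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    chrom = str(df.iloc[0, 0])
    ids = df.iloc[:, 3].astype(str).tolist() if df.shape[1] > 3 else []
    return PeakSet(chrom, df.iloc[:, 1].to_numpy(), df.iloc[:, 2].to_numpy(), ids)


def write_pileup_tsv(pileup: ReadPileup, path: str | Path, chrom: str = "chr1") -> None:
    """Long-form TSV: sample, chrom, pos (1-based), ref_count, alt_count; covered sites only."""
    rows = []
    for i, sid in enumerate(pileup.sample_ids):
        covered = np.flatnonzero(pileup.depth[i] > 0)
        for m in covered:
            rows.append(
                (sid, chrom, int(pileup.positions[m]) + 1, int(pileup.ref_counts[i, m]), int(pileup.alt_counts[i, m]))
            )
    pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref_count", "alt_count"]).to_csv(
        path, sep="\t", index=False
    )


def read_pileup_tsv(path: str | Path, positions: np.ndarray) -> ReadPileup:
    """Read a pileup TSV back onto a fixed site grid (uncovered sites stay zero)."""
    df = pd.read_csv(path, sep="\t")
    samples = sorted(df["sample"].unique().tolist())
    pos_idx = {int(p): m for m, p in enumerate(positions)}
    ref = np.zeros((len(samples), len(positions)), dtype=np.int32)
    alt = np.zeros_like(ref)
    srow = {s: i for i, s in enumerate(samples)}
    for rec in df.itertuples(index=False):
        m = pos_idx.get(int(rec.pos) - 1)
        if m is None:
            raise ValueError(f"pileup site {rec.pos} not on the site grid")
        ref[srow[rec.sample], m] = rec.ref_count
        alt[srow[rec.sample], m] = rec.alt_count
    return ReadPileup(samples, np.asarray(positions), ref, alt)


def write_matrix_tsv(matrix: PeakCountMatrix | CpmMatrix, path: str | Path) -> None:
    values = matrix.counts if isinstance(matrix, PeakCountMatrix) else matrix.values
    pd.DataFrame(values, index=matrix.peak_ids, columns=matrix.sample_ids).to_csv(
        path, sep="\t", index_label="peak_id"
    )


def read_matrix_tsv(path: str | Path, as_counts: bool = True):
    df = pd.read_csv(path, sep="\t", index_col="peak_id")
    cls = PeakCountMatrix if as_counts else CpmMatrix
    return cls(df.to_numpy(), df.index.tolist(), df.columns.tolist())


def write_phenotype_bed(cpm: CpmMatrix, peaks: PeakSet, path: str | Path) -> None:
    """BED-like phenotype table: chrom, start, end, peak_id, one column per donor."""
    order = {pid: i for i, pid in enumerate(cpm.peak_ids)}
    rows = [order[pid] for pid in peaks.peak_ids if pid in order]
    kept = [pid for pid in peaks.peak_ids if pid in order]
    sel = [i for i, pid in enumerate(peaks.peak_ids) if pid in order]
    df = pd.DataFrame(cpm.values[rows], columns=cpm.sample_ids)
    df.insert(0, "peak_id", kept)
    df.insert(0, "end", peaks.ends[sel])
    df.insert(0, "start", peaks.starts[sel])
    df.insert(0, "chrom", peaks.chrom)
    df.to_csv(path, sep="\t", index=False)


def read_phenotype_bed(path: str | Path) -> tuple[CpmMatrix, PeakSet]:
    df = pd.read_csv(path, sep="\t")
    meta = df[["chrom", "start", "end", "peak_id"]]
    donors = [c for c in df.columns if c not in meta.columns]
    peaks = PeakSet(
        str(meta["chrom"].iloc[0]),
        meta["start"].to_numpy(),
        meta["end"].to_numpy(),
        meta["peak_id"].astype(str).tolist(),
    )
    return CpmMatrix(df[donors].to_numpy(), peaks.peak_ids, donors), peaks
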