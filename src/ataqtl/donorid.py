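"""Donor identity resolution from called genotypes.

Public repositories routinely contain several samples from the same donor
(or cell line).  Samples from one donor share a genotype, so the Spearman
correlation of genotype dosages between samples is near 1 for same-donor
pairs and near the relatedness-zero baseline otherwise.  Donors are the
connected components of the thresholded correlation graph, and phenotypes
are averaged to one record per donor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

from .genotype import DosageMatrix
from .peakcall import CpmMatrix

__all__ = [
    "DonorAssignment",
    "pairwise_dosage_correlation",
    "assign_donors",
    "aggregate_by_donor",
]


class DonorAssignment:
    """Partition of samples into donors with the supporting correlations."""

    def __init__(self, sample_ids: list[str], donor_of: dict[str, str], corr: np.ndarray):
        self.sample_ids = list(sample_ids)
        self.donor_of = dict(donor_of)
        self.corr = corr
        if set(self.donor_of) != set(self.sample_ids):
            raise ValueError("assignment must cover every sample exactly once")

    @property
    def donor_ids(self) -> list[str]:
        return sorted(set(self.donor_of.values()))

    @property
    def n_donors(self) -> int:
        return len(set(self.donor_of.values()))

    def members(self, donor_id: str) -> list[str]:
        return [s for s in self.sample_ids if self.donor_of[s] == donor_id]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "donor_id": [self.donor_of[s] for s in self.sample_ids]}
        )


def pairwise_dosage_correlation(
    dosages: DosageMatrix, min_shared: int = 10, af: np.ndarray | None = None
) -> np.ndarray:
    """Spearman correlation of called genotypes between all sample pairs.

    Dosages are AF-centered before rank correlation: raw genotypes of
    *unrelated* individuals correlate strongly through shared allele
    frequencies (everyone carries more alt alleles at common-alt sites);
    subtracting twice the allele frequency puts unrelated pairs near 0 and
    same-donor pairs near 1 -- the bimodal structure the donor-merge
    threshold relies on.  Posterior dosages are used as-is: for samples of
    one donor the panel-shrinkage component at sparsely covered sites is
    shared signal, and rounding it away only weakens their correlation.

    ``af`` supplies an external (e.g. panel) allele frequency; by default
    the cohort's own per-site mean is used, which requires a cohort large
    enough that no single sample dominates the mean.  Pairs sharing fewer
    than ``min_shared`` non-missing sites are NaN.
    """
    X = dosages.dosage
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if af is not None:
        centered = X - 2.0 * np.asarray(af, dtype=float)[None, :]
    else:
        centered = X - np.nanmean(X, axis=0, keepdims=True)  # mean call = 2 * AF
    missing = np.isnan(X)
    if not missing.any():
        ranks = np.apply_along_axis(rankdata, 1, centered)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(ranks)
        np.fill_diagonal(corr, 1.0)
        return corr
    corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~missing[i] & ~missing[j]
            if ok.sum() < min_shared:
                continue
            xi, xj = rankdata(centered[i, ok]), rankdata(centered[j, ok])
            if xi.std() == 0 or xj.std() == 0:
                continue
            corr[i, j] = corr[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    return corr


def assign_donors(
    corr: np.ndarray, sample_ids: list[str], tau: float = 0.8
) -> DonorAssignment:
    """Donors as connected components of the correlation graph at threshold tau.

    Transitive closure is deliberate: one low-coverage sample may correlate
    weakly with some of its siblings yet strongly with another, and the
    chain still identifies a single donor.  Missing correlations count as
    below threshold.  Donor labels are the lexicographically smallest member
    sample id, so output is deterministic.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    n = len(sample_ids)
    adj = np.nan_to_num(corr, nan=-np.inf) >= tau
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    donor_of = {}
    for comp in range(n_comp):
        members = [sample_ids[i] for i in np.flatnonzero(labels == comp)]
        name = min(members)
        for s in members:
            donor_of[s] = name
    return DonorAssignment(sample_ids, donor_of, corr)


def aggregate_by_donor(cpm: CpmMatrix, assign: DonorAssignment) -> CpmMatrix:
    """Average each donor's sample CPMs to one value per peak per donor."""
    donor_ids = assign.donor_ids
    col = {s: j for j, s in enumerate(cpm.sample_ids)}
    out = np.empty((cpm.values.shape[0], len(donor_ids)))
    for k, d in enumerate(donor_ids):
        cols = [col[s] for s in assign.members(d)]
        if not cols:
            raise ValueError(f"donor {d} has no samples")
        out[:, k] = cpm.values[:, cols].mean(axis=1)
    return CpmMatrix(out, list(cpm.peak_ids), donor_ids)
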