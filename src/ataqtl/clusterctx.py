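"""Context clusters: group samples by accessibility profile, re-map caQTLs.

Samples are embedded in 2-D from their log CPM profiles (deterministic PCA
reference embedding; any 2-D embedder with the same contract can be
swapped in), clustered with k-means, and caQTL mapping is re-run within
each cluster.  Cross-cluster replication is summarized as a pi1 matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .genotype import DosageMatrix
from .peakcall import CpmMatrix, PeakCountMatrix, PeakSet
from .qtlmap import QtlConfig, map_caqtls
from .repstats import pi1

__all__ = [
    "ClusterAssignment",
    "embed_samples",
    "kmeans_clusters",
    "cluster_peak_filter",
    "map_cluster_caqtls",
]

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, 2)
    labels: np.ndarray  # int per sample
    k: int
    outlier: np.ndarray = field(default=None)  # bool per sample

    def __post_init__(self) -> None:
        if self.outlier is None:
            self.outlier = np.zeros(len(self.sample_ids), dtype=bool)

    def members(self, cluster: int) -> list[str]:
        keep = (self.labels == cluster) & ~self.outlier
        return [s for s, k in zip(self.sample_ids, keep) if k]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "cluster": self.labels,
                "outlier": self.outlier,
            }
        )


def embed_samples(cpm: CpmMatrix, dims: int = 2, seed: int = 0) -> np.ndarray:
    """Deterministic 2-D embedding of samples from log CPM profiles.

    log2(CPM+1) values are feature-standardized and projected onto the top
    principal components with a fixed sign convention.  PCA is the reference
    embedding because it is exactly reproducible; it preserves separation of
    well-separated sample groups, which is all downstream clustering needs.
    """
    from .qtlmap import compute_pcs

    n_samples = len(cpm.sample_ids)
    if n_samples < dims + 1:
        raise ValueError("need more samples than embedding dimensions")
    X = np.log2(cpm.values.T + 1.0)  # samples x peaks
    return compute_pcs(X, dims, scale=True)


def kmeans_clusters(
    coords: np.ndarray,
    k: int | None = None,
    k_grid: list[int] | None = None,
    seed: int = 0,
    outlier_percentile: float = 99.5,
) -> ClusterAssignment:
    """K-means on the 2-D embedding, with silhouette-based k selection.

    When ``k_grid`` is given, the k maximizing mean silhouette wins.
    Samples whose distance to the nearest centroid exceeds the
    ``outlier_percentile`` of all such distances are flagged outliers and
    excluded from cluster membership.
    """
    coords = np.asarray(coords)
    n = coords.shape[0]
    if k is None and not k_grid:
        raise ValueError("give either k or k_grid")
    if k_grid:
        best, best_score = None, -np.inf
        for kk in k_grid:
            if kk < 2 or kk > n - 1:
                continue
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(coords)
            score = silhouette_score(coords, km.labels_)
            if score > best_score:
                best, best_score = kk, score
        k = best
    if k is None or k > n:
        raise ValueError("no feasible cluster count")
    if k == 1:
        labels = np.zeros(n, dtype=int)
        centroid = coords.mean(axis=0, keepdims=True)
        dist = np.linalg.norm(coords - centroid, axis=1)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(coords)
        labels = km.labels_
        dist = np.linalg.norm(coords - km.cluster_centers_[labels], axis=1)
    cutoff = np.percentile(dist, outlier_percentile)
    outlier = dist > cutoff
    sample_ids = [f"s{i}" for i in range(n)]
    return ClusterAssignment(sample_ids, coords, labels, int(k), outlier)


def cluster_peak_filter(
    counts: PeakCountMatrix | CpmMatrix,
    assign: ClusterAssignment,
    frac: float = 0.5,
) -> dict[int, list[str]]:
    """Per cluster, peaks with non-zero signal in at least ``frac`` of its samples."""
    values = counts.counts if isinstance(counts, PeakCountMatrix) else counts.values
    col = {s: j for j, s in enumerate(counts.sample_ids)}
    out: dict[int, list[str]] = {}
    for c in sorted(set(assign.labels.tolist())):
        member_cols = [col[s] for s in assign.members(c) if s in col]
        if not member_cols:
            out[c] = []
            continue
        nz_frac = (values[:, member_cols] > 0).mean(axis=1)
        out[c] = [p for p, ok in zip(counts.peak_ids, nz_frac >= frac) if ok]
    return out


def map_cluster_caqtls(
    donor_cpm_by_cluster: dict[int, CpmMatrix],
    dosages: DosageMatrix,
    peaks: PeakSet,
    cfg: QtlConfig,
    min_donors: int = 20,
) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Run caQTL mapping within each cluster; cross-cluster pi1 replication.

    ``donor_cpm_by_cluster`` maps a cluster label to the donor-level CPM
    matrix of that cluster's donors (columns are donor ids present in
    ``dosages``).  The replication matrix entry (i, j) is the pi1 of cluster
    i's significant peaks evaluated on cluster j's empirical p-values; the
    diagonal is 1 by construction and reported as NaN.
    """
    results: dict[int, pd.DataFrame] = {}
    for c, cpm in sorted(donor_cpm_by_cluster.items()):
        if len(cpm.sample_ids) < min_donors:
            log.info("cluster %s skipped: %d donors < %d", c, len(cpm.sample_ids), min_donors)
            continue
        idx = [dosages.sample_ids.index(d) for d in cpm.sample_ids]
        sub = DosageMatrix(list(cpm.sample_ids), dosages.positions, dosages.dosage[idx])
        results[c] = map_caqtls(cpm, sub, peaks, cfg)

    clusters = sorted(results)
    mat = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    for ci in clusters:
        sig = results[ci].loc[results[ci]["significant"].fillna(False), "peak_id"]
        for cj in clusters:
            if ci == cj:
                continue
            other = results[cj].set_index("peak_id")["p_empirical"]
            p = other.reindex(sig).dropna().to_numpy()
            if p.size >= 10:
                mat.loc[ci, cj] = pi1(p).pi1
    return results, mat
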