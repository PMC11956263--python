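"""Joint peak calling across samples and peak quantification.

Accessible-chromatin peaks are called jointly over all samples: each sample
contributes a per-bin p-value against its own Poisson background rate, the
per-sample p-values are combined with Fisher's method, and bins passing a
Benjamini-Hochberg threshold are merged into peaks.  Peaks are then
quantified per sample and CPM-normalized against the in-peak library size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PeakSet",
    "PeakCountMatrix",
    "CpmMatrix",
    "per_sample_bin_pvalues",
    "fisher_combine",
    "call_peaks",
    "quantify",
    "filter_peaks",
    "cpm_normalize",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Sorted, non-overlapping peak intervals (0-based, half-open).

    Parameters
    ----------
    chrom : str
        Chromosome label shared by all peaks.
    starts, ends : ndarray of int
        Interval bounds, ``starts[i] < ends[i]``, sorted and non-overlapping.
    peak_ids : list of str
        Stable identifiers, one per interval.
    combined_q : ndarray of float, optional
        BH q-value of the peak (min over member bins) when called from data.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    peak_ids: list[str] = field(default_factory=list)
    combined_q: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not self.peak_ids:
            self.peak_ids = [f"peak_{i}" for i in range(len(self.starts))]
        if np.any(self.starts >= self.ends):
            raise ValueError("peak with start >= end")
        if np.any(np.diff(self.starts) < 0):
            raise ValueError("peaks must be sorted by start")
        if np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("peaks must be non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def to_dataframe(self) -> pd.DataFrame:
        q = self.combined_q if self.combined_q is not None else np.ones(len(self))
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "peak_id": self.peak_ids,
                "q": q,
            }
        )


@dataclass
class PeakCountMatrix:
    """Peaks x samples matrix of non-negative integer read counts."""

    counts: np.ndarray  # (n_peaks, n_samples)
    peak_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("negative peak counts")

    @property
    def library_sizes(self) -> np.ndarray:
        """In-peak total per sample (column sums)."""
        return self.counts.sum(axis=0)

    def subset_peaks(self, keep: np.ndarray) -> "PeakCountMatrix":
        return PeakCountMatrix(
            self.counts[keep],
            [p for p, k in zip(self.peak_ids, keep) if k]
            if keep.dtype == bool
            else [self.peak_ids[i] for i in keep],
            list(self.sample_ids),
        )


@dataclass
class CpmMatrix:
    """Peaks x samples counts-per-million values."""

    values: np.ndarray
    peak_ids: list[str]
    sample_ids: list[str]


# ---------------------------------------------------------------------------
# per-sample evidence
# ---------------------------------------------------------------------------

def per_sample_bin_pvalues(
    coverage: np.ndarray,
    lambda_bg: np.ndarray | float | None = None,
    *,
    bin_size: int = 50,
    chrom_length: int | None = None,
) -> np.ndarray:
    """Upper-tail Poisson p-value per bin per sample.

    ``coverage`` is a (n_bins, n_samples) matrix of read counts.  The
    background rate per bin is estimated per sample as
    ``total_reads * bin_size / chrom_length`` unless given explicitly.
    """
    coverage = np.asarray(coverage)
    if lambda_bg is None:
        if chrom_length is None or chrom_length <= 0:
            raise ValueError("chrom_length must be positive to estimate background")
        lambda_bg = coverage.sum(axis=0) * bin_size / chrom_length
    lam = np.broadcast_to(np.atleast_1d(np.asarray(lambda_bg, dtype=float)), (coverage.shape[1],))
    if np.any(lam <= 0):
        raise ValueError("background rate must be positive")
    # P(X >= k | lam) = sf(k - 1)
    return stats.poisson.sf(coverage - 1, lam[None, :])


def fisher_combine(p_values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Combine p-values with Fisher's method.

    X = -2 * sum(ln p_i) is referred to a chi-square distribution with 2k
    degrees of freedom.  Zero p-values are clamped to the smallest positive
    float with a warning (a zero would make X infinite).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-value clamped to smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    k = p.shape[axis]
    x = -2.0 * np.log(p).sum(axis=axis)
    return stats.chi2.sf(x, 2 * k)


def call_peaks(
    combined_p: np.ndarray,
    *,
    bin_size: int = 50,
    chrom: str = "chr1",
    q_threshold: float = 0.05,
    merge_gap: int = 100,
    blacklist: list[tuple[int, int]] | None = None,
) -> PeakSet:
    """Call peaks from per-bin Fisher-combined p-values.

    BH q-values are computed over all bins; significant bins (q <= threshold)
    outside the blacklist are merged into peaks when separated by at most
    ``merge_gap`` bp.
    """
    combined_p = np.asarray(combined_p, dtype=float)
    n_bins = combined_p.size
    reject, qvals, _, _ = multipletests(combined_p, alpha=q_threshold, method="fdr_bh")[0:4]
    sig = qvals <= q_threshold
    if blacklist:
        starts_bp = np.arange(n_bins) * bin_size
        ends_bp = starts_bp + bin_size
        for b0, b1 in blacklist:
            sig &= ~((starts_bp < b1) & (ends_bp > b0))
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return PeakSet(chrom, np.array([], dtype=np.int64), np.array([], dtype=np.int64) + 1, [])
    gap_bins = max(1, merge_gap // bin_size)
    breaks = np.flatnonzero(np.diff(idx) > gap_bins)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [idx.size - 1]])
    starts, ends, qmin = [], [], []
    for a, b in zip(run_starts, run_ends):
        starts.append(idx[a] * bin_size)
        ends.append((idx[b] + 1) * bin_size)
        qmin.append(qvals[idx[a] : idx[b] + 1].min())
    return PeakSet(
        chrom,
        np.array(starts),
        np.array(ends),
        [f"peak_{i}" for i in range(len(starts))],
        combined_q=np.array(qmin),
    )


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def quantify(
    read_positions: dict[str, np.ndarray],
    peaks: PeakSet,
) -> PeakCountMatrix:
    """Count reads per peak per sample (half-open intervals: start in, end out)."""
    sample_ids = list(read_positions)
    counts = np.zeros((len(peaks), len(sample_ids)), dtype=np.int64)
    for j, sid in enumerate(sample_ids):
        pos = np.asarray(read_positions[sid])
        if pos.size == 0:
            continue
        lo = np.searchsorted(peaks.starts, pos, side="right") - 1
        ok = (lo >= 0) & (pos < peaks.ends[np.clip(lo, 0, None)])
        np.add.at(counts[:, j], lo[ok], 1)
    return PeakCountMatrix(counts, list(peaks.peak_ids), sample_ids)


def filter_peaks(
    counts: PeakCountMatrix,
    *,
    mean_min: float = 1.0,
    max_max: float = 100_000.0,
    zero_frac: float = 5000 / 10293,
) -> PeakCountMatrix:
    """Drop outlier peaks by mean, max, and zero-count-fraction rules."""
    c = counts.counts
    mean_ok = c.mean(axis=1) >= mean_min
    max_ok = c.max(axis=1) <= max_max
    zero_ok = (c == 0).mean(axis=1) <= zero_frac
    keep = mean_ok & max_ok & zero_ok
    if not keep.any():
        warnings.warn("all peaks removed by filtering")
    return counts.subset_peaks(keep)


def cpm_normalize(counts: PeakCountMatrix) -> CpmMatrix:
    """Counts-per-million against the in-peak library size."""
    lib = counts.library_sizes.astype(float)
    bad = np.flatnonzero(lib == 0)
    if bad.size:
        raise ValueError(
            f"zero library size for sample(s): {[counts.sample_ids[i] for i in bad]}"
        )
    values = counts.counts / lib[None, :] * 1e6
    return CpmMatrix(values, list(counts.peak_ids), list(counts.sample_ids))
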