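"""Replication and enrichment statistics.

pi1 replication rates (Storey's 1 - pi0, medianed over a lambda grid),
matched-background variant sampling for lead-variant enrichment, interval
shuffling against a blacklist, and annotation overlap labeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Pi1Result",
    "EnrichmentResult",
    "pi1",
    "matched_background_variants",
    "enrichment",
    "shuffle_intervals",
    "annotate_regions",
]

log = logging.getLogger(__name__)

PI1_LAMBDA_GRID = np.round(np.arange(0.1, 0.9001, 0.05), 2)


@dataclass
class Pi1Result:
    lambda_grid: np.ndarray
    pi0_estimates: np.ndarray
    pi1: float
    m: int


@dataclass
class EnrichmentResult:
    observed: int
    background: np.ndarray  # overlap count per iteration
    fold: float
    p: float


def pi1(p_values: np.ndarray, lambda_grid: np.ndarray | None = None) -> Pi1Result:
    """Replication rate pi1 = 1 - median over the lambda grid of pi0(lambda).

    pi0(lambda) = #{p > lambda} / ((1 - lambda) m), clamped to [0, 1]; the
    clamp matters at small m where the raw estimator can exceed 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    grid = PI1_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    pi0 = np.clip([(p > lam).sum() / ((1 - lam) * p.size) for lam in grid], 0.0, 1.0)
    return Pi1Result(grid, pi0, float(1.0 - np.median(pi0)), p.size)


def matched_background_variants(
    leads: "pd.DataFrame",
    pool: "pd.DataFrame",
    *,
    af_tol: float = 0.10,
    tss_tol: float = 0.10,
    n_iter: int = 100,
    seed: int = 0,
    relative: bool = True,
) -> list[list[str]]:
    """Background variant sets matched to leads on AF and TSS distance.

    For each lead, one pool variant with allele frequency within +-10%
    (relative by default) and |TSS distance| within +-10% is drawn per
    iteration.  Leads with no eligible match are skipped (count logged);
    more than 20% unmatched warns, 100% unmatched raises.
    """
    rng = np.random.default_rng(seed)
    pool_ids = pool["variant_id"].to_numpy()
    pool_af = pool["af"].to_numpy(dtype=float)
    pool_tss = np.abs(pool["tss_distance"].to_numpy(dtype=float))
    if np.isin(leads["variant_id"], pool_ids).any():
        raise ValueError("pool must exclude the lead variants")

    eligible: list[np.ndarray] = []
    n_unmatched = 0
    for _, row in leads.iterrows():
        af, tss = float(row["af"]), abs(float(row["tss_distance"]))
        if relative:
            af_ok = np.abs(pool_af - af) <= af_tol * af
            tss_ok = np.abs(pool_tss - tss) <= tss_tol * tss if tss > 0 else pool_tss == 0
        else:
            af_ok = np.abs(pool_af - af) <= af_tol
            tss_ok = np.abs(pool_tss - tss) <= tss_tol
        idx = np.flatnonzero(af_ok & tss_ok)
        if idx.size == 0:
            n_unmatched += 1
        else:
            eligible.append(idx)
    if n_unmatched == len(leads):
        raise ValueError("no lead variant could be matched in the pool")
    if n_unmatched > 0.2 * len(leads):
        warnings.warn(f"{n_unmatched}/{len(leads)} lead variants unmatched")
    elif n_unmatched:
        log.info("%d lead variants had no matched background", n_unmatched)

    sets = []
    for _ in range(n_iter):
        sets.append([str(pool_ids[rng.choice(idx)]) for idx in eligible])
    return sets


def enrichment(
    leads: set[str],
    backgrounds: list[list[str]],
    target: set[str],
) -> EnrichmentResult:
    """Fold enrichment of lead overlap with a target set over matched backgrounds.

    fold = observed / mean(background); empirical p uses the +1/(n+1)
    correction so a p of exactly zero is impossible.
    """
    observed = len(leads & target)
    bg = np.array([len(set(b) & target) for b in backgrounds])
    mean_bg = bg.mean()
    fold = observed / mean_bg if mean_bg > 0 else np.nan
    p = (1.0 + np.sum(bg >= observed)) / (len(bg) + 1.0)
    return EnrichmentResult(observed, bg, float(fold), float(p))


def shuffle_intervals(
    intervals: list[tuple[str, int, int]],
    chrom_sizes: dict[str, int],
    blacklist: list[tuple[str, int, int]] | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> list[tuple[str, int, int]]:
    """Re-place each interval uniformly at random on its own chromosome.

    Lengths are preserved exactly; placements overlapping the blacklist are
    rejected and redrawn (up to ``max_tries`` per interval).
    """
    rng = np.random.default_rng(seed)
    bl: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in blacklist or []:
        bl.setdefault(c, []).append((s, e))
    out = []
    for chrom, start, end in intervals:
        length = end - start
        size = chrom_sizes[chrom]
        if length > size:
            raise ValueError(f"interval {chrom}:{start}-{end} longer than its chromosome")
        placed = None
        for _ in range(max_tries):
            s = int(rng.integers(0, size - length + 1))
            e = s + length
            if any(s < b1 and e > b0 for b0, b1 in bl.get(chrom, [])):
                continue
            placed = (chrom, s, e)
            break
        if placed is None:
            raise ValueError(
                f"could not place interval {chrom}:{start}-{end} outside the blacklist"
            )
        out.append(placed)
    return out


def annotate_regions(
    intervals: list[tuple[str, int, int]],
    annotations: dict[str, list[tuple[str, int, int]]],
    min_overlap: int = 200,
) -> list[set[str]]:
    """Label each interval with every annotation track it overlaps by >= min_overlap bp.

    Strand is ignored; an interval can receive multiple labels.
    """
    labels: list[set[str]] = []
    for chrom, s, e in intervals:
        got = set()
        for name, track in annotations.items():
            for tc, ts, te in track:
                if tc != chrom:
                    continue
                if min(e, te) - max(s, ts) >= min_overlap:
                    got.add(name)
                    break
        labels.append(got)
    return labels
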