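"""Bayesian colocalization of pairs of association signals.

Implements the single-causal-variant colocalization model on Wakefield
approximate Bayes factors: per-variant ABFs for each trait are combined
over the five hypothesis configurations (H0 no causal variant; H1/H2 causal
for one trait only; H3 two distinct causal variants; H4 one shared causal
variant) and normalized to posterior probabilities PP0-PP4.  A locus is
declared colocalized when PP3 + PP4 > 0.8 and PP4 / (PP3 + PP4) > 0.9.
Also provides GWAS lead-signal selection with LD clumping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "SummaryStatSet",
    "ColocResult",
    "GwasLead",
    "wakefield_log_abf",
    "coloc_posteriors",
    "coloc_decision",
    "select_gwas_leads",
    "coloc_locus_window",
]


@dataclass
class SummaryStatSet:
    """Per-variant association summary statistics for one trait at one locus."""

    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    af: np.ndarray
    n: np.ndarray
    trait_type: str = "quantitative"  # or "cc" (case-control)
    locus_id: str = ""
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    def prior_sd(self) -> float:
        """Prior effect sd: 0.15 for quantitative traits, 0.2 for case-control."""
        return 0.2 if self.trait_type == "cc" else 0.15


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: tuple[float, float, float]

    @property
    def pp(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


@dataclass
class GwasLead:
    variant_id: str
    p: float
    members: list[str]
    window: int


def wakefield_log_abf(beta: np.ndarray, se: np.ndarray, W: float) -> np.ndarray:
    """Log approximate Bayes factor for H1 (variant causal) vs H0.

    With V = se^2 and z = beta/se:
    log ABF = 0.5 log(V / (V + W)) + 0.5 z^2 W / (V + W).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or W <= 0:
        raise ValueError("se and W must be positive")
    V = se**2
    z2 = (beta / se) ** 2
    r = W / (V + W)
    return 0.5 * np.log(V / (V + W)) + 0.5 * z2 * r


def _logdiffexp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b, -inf when equal within rounding."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_posteriors(
    set1: SummaryStatSet,
    set2: SummaryStatSet,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Posterior probabilities PP0-PP4 under the single-causal-variant model.

    Operates on the variants shared by the two sets (matched by id).  All
    sums are carried in log space; with a single shared variant PP3 is
    exactly zero (no configuration places two distinct causal variants).
    """
    ids1 = {v: i for i, v in enumerate(set1.variant_ids)}
    shared = [v for v in set2.variant_ids if v in ids1]
    if not shared:
        raise ValueError("no shared variants between the two sets")
    i1 = np.array([ids1[v] for v in shared])
    i2 = np.array([set2.variant_ids.index(v) for v in shared])

    l1 = wakefield_log_abf(set1.beta[i1], set1.se[i1], set1.prior_sd() ** 2)
    l2 = wakefield_log_abf(set2.beta[i2], set2.se[i2], set2.prior_sd() ** 2)
    n = len(shared)

    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    # sum over ordered pairs (i, j), i != j: (sum_i e^l1)(sum_j e^l2) - sum_i e^(l1+l2)
    lh = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            (np.log(p1) + np.log(p2) + _logdiffexp(s1 + s2, s12)) if n > 1 else -np.inf,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(*pp.tolist(), n_snps=n, priors=(p1, p2, p12))


def coloc_enumeration_oracle(
    l1: np.ndarray, l2: np.ndarray, p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5
) -> np.ndarray:
    """Direct sum over all single-variant configurations (test reference).

    Enumerates every causal-variant placement explicitly in linear space;
    only suitable for small loci.
    """
    b1 = np.exp(np.asarray(l1))
    b2 = np.exp(np.asarray(l2))
    n = b1.size
    h0 = 1.0
    h1 = p1 * b1.sum()
    h2 = p2 * b2.sum()
    h3 = p1 * p2 * sum(b1[i] * b2[j] for i in range(n) for j in range(n) if i != j)
    h4 = p12 * float((b1 * b2).sum())
    raw = np.array([h0, h1, h2, h3, h4])
    return raw / raw.sum()


def coloc_decision(r: ColocResult) -> bool:
    """Declared colocalized iff PP3+PP4 > 0.8 and PP4/(PP3+PP4) > 0.9."""
    s = r.pp3 + r.pp4
    if s == 0.0 or s <= 0.8:
        return False
    return r.pp4 / s > 0.9


def select_gwas_leads(
    stats: SummaryStatSet,
    dosages: np.ndarray,
    positions: np.ndarray,
    *,
    p_thresh: float = 5e-8,
    window: int = 50_000,
    r2_thresh: float = 0.01,
) -> list[GwasLead]:
    """Iterative lead selection with LD clumping.

    Repeatedly takes the most significant remaining variant with p below
    threshold as a lead, then removes every variant within +-window bp whose
    dosage r^2 with the lead exceeds ``r2_thresh``.
    """
    from scipy.stats import norm

    z = np.abs(stats.z)
    pvals = 2.0 * norm.sf(z)
    positions = np.asarray(positions)
    G = np.asarray(dosages, dtype=float)
    available = np.ones(len(stats.variant_ids), dtype=bool)
    leads: list[GwasLead] = []
    while True:
        cand = np.flatnonzero(available & (pvals <= p_thresh))
        if cand.size == 0:
            break
        lead = cand[np.argmin(pvals[cand])]
        near = np.flatnonzero(available & (np.abs(positions - positions[lead]) <= window))
        g_lead = G[:, lead]
        members = [stats.variant_ids[lead]]
        for j in near:
            if j == lead:
                continue
            sd = G[:, j].std()
            if sd == 0 or g_lead.std() == 0:
                continue
            r2 = float(np.corrcoef(g_lead, G[:, j])[0, 1] ** 2)
            if r2 > r2_thresh:
                members.append(stats.variant_ids[j])
                available[j] = False
        available[lead] = False
        leads.append(GwasLead(stats.variant_ids[lead], float(pvals[lead]), members, window))
    return leads


def coloc_locus_window(
    peak_start: int, peak_end: int, window: int = 10_000, chrom_length: int | None = None
) -> tuple[int, int]:
    """Colocalization interval: peak extended by ``window`` bp, clipped to the chromosome."""
    lo = max(0, peak_start - window)
    hi = peak_end + window
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi
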