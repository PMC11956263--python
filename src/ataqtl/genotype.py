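"""Genotype inference from sparse per-site read pileups.

ATAC-seq reads concentrate in accessible chromatin, so a sample's reads
touch only a small fraction of the polymorphic sites of a reference panel.
This module turns those sparse pileups into genome-wide genotype dosages:

1. binomial genotype likelihoods at every covered site
   (:func:`pileup_likelihoods`);
2. maximum-likelihood direct calls at sufficiently covered sites
   (:func:`direct_call`);
3. imputation of all panel sites with a diploid Li-Stephens copying HMM
   (:func:`impute`), whose hidden state is an ordered pair of panel
   haplotypes and whose emissions weight each possible true genotype by the
   site's likelihood triplet;
4. a learned combiner that arbitrates between direct and imputed calls at
   discordant sites (:func:`train_combiner`);
5. concordance metrics against a truth set (:func:`genotype_concordance`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ReadPileup",
    "GenotypeLikelihoods",
    "DosageMatrix",
    "ImputationParams",
    "CombinerModel",
    "pileup_likelihoods",
    "direct_call",
    "effective_coverage",
    "impute",
    "train_combiner",
    "genotype_concordance",
]

MISSING = -1  # hard-call sentinel


@dataclass
class ReadPileup:
    """Per sample x site reference/alternate read counts."""

    sample_ids: list[str]
    positions: np.ndarray  # site coordinates, aligned to the panel
    ref_counts: np.ndarray  # (n_samples, n_sites)
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts)
        self.alt_counts = np.asarray(self.alt_counts)
        if np.any(self.ref_counts < 0) or np.any(self.alt_counts < 0):
            raise ValueError("negative read counts")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts


@dataclass
class GenotypeLikelihoods:
    """Likelihood triplets P(reads | g) for g in {0, 1, 2} alt alleles.

    Unobserved sites (zero depth) carry the flat triplet (1, 1, 1): no reads
    means no evidence, never certainty.
    """

    sample_ids: list[str]
    positions: np.ndarray
    likelihoods: np.ndarray  # (n_samples, n_sites, 3)
    mask: np.ndarray  # True where depth >= 1

    def __post_init__(self) -> None:
        if np.any(self.likelihoods < 0):
            raise ValueError("negative likelihood")


@dataclass
class DosageMatrix:
    """Samples x sites genotype dosages in [0, 2] with optional hard calls."""

    sample_ids: list[str]
    positions: np.ndarray
    dosage: np.ndarray  # float, NaN = missing
    hard_call: np.ndarray | None = None  # int8, MISSING = -1

    def __post_init__(self) -> None:
        d = self.dosage
        with np.errstate(invalid="ignore"):
            if np.any((d < -1e-9) | (d > 2 + 1e-9)):
                raise ValueError("dosage outside [0, 2]")

    @property
    def af(self) -> np.ndarray:
        """Per-site alternate-allele frequency, mean(dosage)/2 over non-missing."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        af = self.af
        return np.minimum(af, 1.0 - af)


@dataclass
class ImputationParams:
    """Li-Stephens HMM parameters.

    switch_rate : per-site probability that a copied haplotype switches to a
        uniformly chosen panel template.
    copy_error : probability that a copied allele mismatches its template.
    eps : per-read sequencing error used when likelihoods are recomputed.
    """

    switch_rate: float = 0.002
    copy_error: float = 0.01
    eps: float = 0.01

    def __post_init__(self) -> None:
        for name in ("switch_rate", "copy_error", "eps"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# likelihoods and direct calls
# ---------------------------------------------------------------------------

def pileup_likelihoods(pileup: ReadPileup, eps: float = 0.01) -> GenotypeLikelihoods:
    """Binomial genotype likelihoods from ref/alt read counts.

    With depth d = r + a the likelihood of g alt alleles is
    ``C(d, a) p_g^a (1 - p_g)^(d - a)`` with alt-read probabilities
    p_0 = eps, p_1 = 1/2, p_2 = 1 - eps.  A uniform genotype prior is kept
    out of this function; panel information enters only through the HMM.
    """
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    r = pileup.ref_counts.astype(float)
    a = pileup.alt_counts.astype(float)
    d = r + a
    log_comb = special.gammaln(d + 1) - special.gammaln(a + 1) - special.gammaln(r + 1)
    lik = np.empty(r.shape + (3,), dtype=float)
    for g, p in enumerate((eps, 0.5, 1.0 - eps)):
        lik[..., g] = np.exp(log_comb + a * np.log(p) + r * np.log1p(-p))
    mask = d >= 1
    lik[~mask] = 1.0
    return GenotypeLikelihoods(list(pileup.sample_ids), pileup.positions, lik, mask)


def direct_call(gl: GenotypeLikelihoods, min_depth: int = 2, *, depth: np.ndarray | None = None) -> DosageMatrix:
    """Posterior-mean dosage and hard call under a uniform prior.

    Sites with fewer than ``min_depth`` reads are reported missing, matching
    the convention of filtering loci with <2 reads before benchmarking.
    ``depth`` defaults to 1 at observed sites when no pileup depth is given,
    which makes ``min_depth=1`` the only sensible value in that case.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    lik = gl.likelihoods
    tot = lik.sum(axis=-1)
    dosage = (lik[..., 1] + 2.0 * lik[..., 2]) / tot
    hard = np.argmax(lik, axis=-1).astype(np.int8)
    if depth is None:
        observed = gl.mask if min_depth == 1 else np.zeros_like(gl.mask)
        if min_depth > 1:
            raise ValueError("min_depth > 1 requires per-site depth")
    else:
        observed = depth >= min_depth
    dosage = np.where(observed, dosage, np.nan)
    hard = np.where(observed, hard, MISSING).astype(np.int8)
    return DosageMatrix(list(gl.sample_ids), gl.positions, dosage, hard)


def effective_coverage(pileup: ReadPileup, panel) -> np.ndarray:
    """Fraction of panel polymorphic sites covered by >= 1 read, per sample."""
    n_panel = len(panel.site_positions)
    if n_panel == 0:
        raise ValueError("empty reference panel")
    if not np.isin(pileup.positions, panel.site_positions).all():
        raise ValueError("pileup sites must be a subset of panel sites")
    covered = (pileup.depth >= 1).sum(axis=1)
    return covered / n_panel


# ---------------------------------------------------------------------------
# diploid Li-Stephens imputation
# ---------------------------------------------------------------------------

def _emission_factors(panel_col: np.ndarray, copy_error: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-haplotype probabilities of emitting allele 0 / allele 1 at a site."""
    mu = copy_error
    u1 = np.where(panel_col == 1, 1.0 - mu, mu)
    return 1.0 - u1, u1


def _pair_transition(f: np.ndarray, s: float) -> np.ndarray:
    """Apply the factorized pair transition to a state matrix.

    Each haplotype independently keeps its template with probability
    ``1 - s + s/n`` and jumps to any template with probability ``s/n``; the
    rank-one structure reduces the O(n^4) pair transition to O(n^2).
    """
    n = f.shape[0]
    stay = 1.0 - s
    jump = s / n
    row = f.sum(axis=0, keepdims=True)  # marginal over first haplotype
    col = f.sum(axis=1, keepdims=True)
    tot = row.sum()
    return stay * stay * f + stay * jump * (row + col) + jump * jump * tot


def impute(
    gl: GenotypeLikelihoods,
    panel,
    params: ImputationParams | None = None,
) -> DosageMatrix:
    """Posterior genotype dosage at every panel site via forward-backward.

    The hidden state is an ordered pair of panel haplotypes; at each site the
    pair emits a true genotype (each copied allele mismatching its template
    with probability ``copy_error``) that is scored against the site's
    genotype-likelihood triplet.  Forward variables are rescaled per site to
    prevent underflow.  Dosage is the posterior mean of the true genotype.
    """
    params = params or ImputationParams()
    H = np.asarray(panel.haplotypes, dtype=np.int8)
    n_hap, n_sites = H.shape
    if gl.likelihoods.shape[1] != n_sites or not np.array_equal(
        np.asarray(gl.positions), np.asarray(panel.site_positions)
    ):
        raise ValueError("genotype likelihoods are not aligned to the panel sites")

    # precompute per-site emission ingredients
    U0 = np.empty((n_sites, n_hap))
    U1 = np.empty((n_sites, n_hap))
    for m in range(n_sites):
        U0[m], U1[m] = _emission_factors(H[:, m], params.copy_error)

    s = params.switch_rate
    n_samples = len(gl.sample_ids)
    dosage = np.empty((n_samples, n_sites))
    # full-precision forward store below ~256 MB, float32 above
    store_dtype = np.float64 if n_sites * n_hap * n_hap <= 32_000_000 else np.float32
    fwd_store = np.empty((n_sites, n_hap, n_hap), dtype=store_dtype)

    for i in range(n_samples):
        L = gl.likelihoods[i]  # (n_sites, 3)
        # --- forward ---
        f = np.full((n_hap, n_hap), 1.0 / (n_hap * n_hap))
        for m in range(n_sites):
            if m > 0:
                f = _pair_transition(f, s)
            u0, u1 = U0[m], U1[m]
            E = (
                L[m, 0] * np.outer(u0, u0)
                + L[m, 1] * (np.outer(u0, u1) + np.outer(u1, u0))
                + L[m, 2] * np.outer(u1, u1)
            )
            f = f * E
            f /= f.sum()
            fwd_store[m] = f
        # --- backward, accumulating genotype posteriors ---
        b = np.ones((n_hap, n_hap))
        for m in range(n_sites - 1, -1, -1):
            if m == 0:
                f_pre = np.full((n_hap, n_hap), 1.0 / (n_hap * n_hap))
            else:
                f_pre = _pair_transition(fwd_store[m - 1].astype(float), s)
            M = f_pre * b
            u0, u1 = U0[m], U1[m]
            q00 = u0 @ M @ u0
            q01 = u0 @ M @ u1 + u1 @ M @ u0
            q11 = u1 @ M @ u1
            post = np.array([L[m, 0] * q00, L[m, 1] * q01, L[m, 2] * q11])
            post /= post.sum()
            dosage[i, m] = post[1] + 2.0 * post[2]
            if m > 0:
                E = (
                    L[m, 0] * np.outer(u0, u0)
                    + L[m, 1] * (np.outer(u0, u1) + np.outer(u1, u0))
                    + L[m, 2] * np.outer(u1, u1)
                )
                b = _pair_transition(b * E, s)
                b /= b.sum()

    hard = np.clip(np.round(dosage), 0, 2).astype(np.int8)
    return DosageMatrix(list(gl.sample_ids), np.asarray(panel.site_positions), dosage, hard)


def impute_brute_force(
    gl: GenotypeLikelihoods,
    panel,
    params: ImputationParams,
    sample_index: int = 0,
) -> np.ndarray:
    """Exhaustive-path reference for :func:`impute` on tiny instances.

    Enumerates every sequence of haplotype-pair states; exponential in the
    number of sites, usable only as a test oracle.
    """
    H = np.asarray(panel.haplotypes, dtype=np.int8)
    n_hap, n_sites = H.shape
    L = gl.likelihoods[sample_index]
    s = params.switch_rate
    n = n_hap
    trans = np.full((n, n), s / n) + (1.0 - s) * np.eye(n)

    def emission(h1: int, h2: int, m: int) -> np.ndarray:
        """joint P(true genotype g, reads at m | state), per g"""
        u0_1, u1_1 = _emission_factors(H[[h1], m], params.copy_error)
        u0_2, u1_2 = _emission_factors(H[[h2], m], params.copy_error)
        pg = np.array(
            [
                u0_1[0] * u0_2[0],
                u0_1[0] * u1_2[0] + u1_1[0] * u0_2[0],
                u1_1[0] * u1_2[0],
            ]
        )
        return pg * L[m]

    import itertools

    states = list(itertools.product(range(n), repeat=2))
    genotype_weight = np.zeros((n_sites, 3))
    total = 0.0
    for path in itertools.product(states, repeat=n_sites):
        w = 1.0 / (n * n)
        for m in range(1, n_sites):
            w *= trans[path[m - 1][0], path[m][0]] * trans[path[m - 1][1], path[m][1]]
        per_site = [emission(h1, h2, m) for m, (h1, h2) in enumerate(path)]
        sums = np.array([p.sum() for p in per_site])
        path_lik = w * sums.prod()
        total += path_lik
        for m in range(n_sites):
            if sums[m] > 0:
                genotype_weight[m] += path_lik * per_site[m] / sums[m]
    genotype_weight /= total
    return genotype_weight @ np.array([0.0, 1.0, 2.0])


# ---------------------------------------------------------------------------
# combining direct and imputed calls
# ---------------------------------------------------------------------------

@dataclass
class CombinerModel:
    """Arbitrates between direct and imputed genotype calls.

    The fitted decision function returns a weight w in [0, 1] for the direct
    call; the combined dosage is ``w * direct + (1 - w) * imputed``.  At
    zero-depth sites w = 0 (no direct evidence).  When training data is
    degenerate the deterministic fallback rule applies: trust the direct call
    iff depth >= ``fallback_depth``.
    """

    model: LogisticRegression | None = None
    fallback_depth: int = 8
    heldout_mse: float | None = None

    @staticmethod
    def features(depth, gl_margin, imp_margin, agree) -> np.ndarray:
        return np.column_stack(
            [
                np.log1p(depth),
                gl_margin,
                imp_margin,
                agree.astype(float),
            ]
        )

    def weight(self, depth, gl_margin, imp_margin, agree) -> np.ndarray:
        depth = np.asarray(depth, dtype=float)
        if self.model is None:
            w = (depth >= self.fallback_depth).astype(float)
        else:
            X = self.features(depth, gl_margin, imp_margin, agree)
            w = self.model.predict_proba(X)[:, 1]
        return np.where(depth == 0, 0.0, w)

    def combine(
        self,
        direct: DosageMatrix,
        imputed: DosageMatrix,
        depth: np.ndarray,
    ) -> DosageMatrix:
        d = np.nan_to_num(direct.dosage, nan=0.0)
        gl_margin = np.abs(d - np.round(d))
        imp_margin = np.abs(imputed.dosage - np.round(imputed.dosage))
        agree = np.round(d) == np.round(imputed.dosage)
        w = self.weight(
            depth.ravel(), gl_margin.ravel(), imp_margin.ravel(), agree.ravel()
        ).reshape(depth.shape)
        w = np.where(np.isnan(direct.dosage), 0.0, w)
        combined = w * d + (1.0 - w) * imputed.dosage
        hard = np.clip(np.round(combined), 0, 2).astype(np.int8)
        return DosageMatrix(list(imputed.sample_ids), imputed.positions, combined, hard)


def train_combiner(
    direct: DosageMatrix,
    imputed: DosageMatrix,
    truth: DosageMatrix,
    depth: np.ndarray,
    split: float = 0.8,
    seed: int = 0,
) -> CombinerModel:
    """Fit the direct-vs-imputed arbiter on an 80/20 sample split.

    Training examples are sites where the direct and imputed hard calls
    disagree; the label is whether the direct call matches the truth.  The
    held-out MSE of the combined dosage is recorded on the model.
    """
    n_samples = len(direct.sample_ids)
    if n_samples < 10:
        raise ValueError("need >= 10 samples to train the combiner")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    n_train = int(round(split * n_samples))
    train_idx, test_idx = order[:n_train], order[n_train:]

    d_hard = np.where(np.isnan(direct.dosage), MISSING, np.round(direct.dosage))
    i_hard = np.round(imputed.dosage)
    discordant = (d_hard != i_hard) & (d_hard != MISSING)

    rows = np.isin(np.arange(n_samples), train_idx)[:, None] & discordant
    model = CombinerModel()
    if rows.sum() >= 20:
        dep = depth[rows]
        d = direct.dosage[rows]
        gl_margin = np.abs(d - np.round(d))
        imp_margin = np.abs(imputed.dosage[rows] - np.round(imputed.dosage[rows]))
        agree = np.zeros(rows.sum(), dtype=bool)  # discordant by construction
        y = (np.round(d) == truth.dosage[rows]).astype(int)
        if len(np.unique(y)) == 2:
            clf = LogisticRegression(max_iter=1000)
            clf.fit(CombinerModel.features(dep, gl_margin, imp_margin, agree), y)
            model.model = clf
        else:
            warnings.warn("one-class combiner training labels; using depth fallback")
    else:
        warnings.warn("too few discordant loci; using deterministic depth fallback")

    if test_idx.size:
        sub = lambda dm, idx: DosageMatrix(
            [dm.sample_ids[i] for i in idx], dm.positions, dm.dosage[idx]
        )
        combined = model.combine(sub(direct, test_idx), sub(imputed, test_idx), depth[test_idx])
        model.heldout_mse = float(np.nanmean((combined.dosage - truth.dosage[test_idx]) ** 2))
    return model


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def genotype_concordance(called: DosageMatrix, truth: DosageMatrix) -> "pd.DataFrame":
    """Per-sample Spearman correlation and MSE against a truth set.

    Constant called vectors have undefined rank correlation; these are
    reported as NaN, never coerced to 0.
    """
    import pandas as pd

    if called.dosage.shape != truth.dosage.shape:
        raise ValueError("called and truth matrices are not aligned")
    records = []
    for i, sid in enumerate(called.sample_ids):
        c = called.dosage[i]
        t = truth.dosage[i]
        ok = ~np.isnan(c) & ~np.isnan(t)
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 shared non-missing sites for {sid}")
        mse = float(np.mean((c[ok] - t[ok]) ** 2))
        if np.all(c[ok] == c[ok][0]) or np.all(t[ok] == t[ok][0]):
            rho = np.nan
        else:
            rho = float(stats.spearmanr(c[ok], t[ok]).statistic)
        records.append({"sample_id": sid, "spearman": rho, "mse": mse, "n_sites": int(ok.sum())})
    return pd.DataFrame(records)
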