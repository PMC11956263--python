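"""caQTL mapping: cis-window scans, permutation p-values, Storey q-values.

For each accessibility peak, variants within a cis-window of the peak
boundaries (MAF above threshold) are tested against the donor-level
phenotype with a covariate-adjusted linear model.  Peak-level significance
comes from permutations of the covariate-residualized phenotype
(Freedman-Lane), and the peak-level empirical p-values are converted to
q-values with Storey's estimator of the null proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype import DosageMatrix
from .peakcall import CpmMatrix, PeakSet
from .synthdata import stage_rng

__all__ = [
    "QtlConfig",
    "select_cis_variants",
    "compute_pcs",
    "nominal_scan",
    "empirical_peak_pvalue",
    "beta_approx_pvalue",
    "storey_qvalues",
    "choose_phenotype_pcs",
    "map_caqtls",
    "benchmark_precision_recall",
]

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.1, 0.9001, 0.05), 2)


@dataclass
class QtlConfig:
    """Mapping parameters.

    ``n_phenotype_pcs=None`` scales the count with the cohort as
    ``min(0.15 * n_donors, 200)``; large fixed PC counts suit large cohorts
    only.  ``transform`` is ``log2cpm`` (log2(CPM+1)) or ``rint``
    (rank-inverse-normal).
    """

    cis_window: int = 10_000
    maf_min: float = 0.05
    n_genotype_pcs: int = 3
    n_phenotype_pcs: int | None = None
    n_permutations: int = 1000
    fdr: float = 0.05
    transform: str = "log2cpm"
    lambda_grid: np.ndarray = field(default_factory=lambda: DEFAULT_LAMBDA_GRID.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if not (0.0 < self.maf_min < 0.5):
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.n_permutations < 20:
            raise ValueError("need at least 20 permutations")

    def phenotype_pcs_for(self, n_donors: int) -> int:
        if self.n_phenotype_pcs is not None:
            return self.n_phenotype_pcs
        return int(min(round(0.15 * n_donors), 200))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def select_cis_variants(
    peak_start: int,
    peak_end: int,
    dosages: DosageMatrix,
    cfg: QtlConfig,
) -> np.ndarray:
    """Indices of biallelic variants in [start - window, end + window) with MAF > maf_min."""
    pos = np.asarray(dosages.positions)
    lo, hi = peak_start - cfg.cis_window, peak_end + cfg.cis_window
    in_window = (pos >= lo) & (pos < hi)
    maf = dosages.maf
    return np.flatnonzero(in_window & (maf > cfg.maf_min))


def compute_pcs(matrix: np.ndarray, k: int, scale: bool = False) -> np.ndarray:
    """Principal-component scores of a samples x features matrix.

    Features are centered (and optionally unit-scaled); the sign of each
    component is fixed so its largest-magnitude loading is positive,
    making scores deterministic across runs and BLAS builds.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if k >= min(n, p):
        raise ValueError(f"k={k} must be < min(n_samples, n_features)={min(n, p)}")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(S)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    return (U[:, :k] * S[:k]) * flip[:k]


def _covariate_basis(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis of the span of [intercept | covariates].

    Collinear columns are dropped (with a warning) via rank-revealing QR so
    the basis is always well conditioned.
    """
    Z = np.ones((n, 1))
    if covariates is not None and np.asarray(covariates).size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        Z = np.column_stack([Z, C])
    q, r = np.linalg.qr(Z)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(r[0, 0]), 1e-300)
    if not keep.all():
        warnings.warn("dropping collinear covariate column(s)")
    return q[:, keep]


def _residualize(y: np.ndarray, covariates: np.ndarray | None = None, Q: np.ndarray | None = None):
    """Project out covariates (plus intercept); return residuals and rank used."""
    if Q is None:
        Q = _covariate_basis(covariates, y.shape[0])
    return y - Q @ (Q.T @ y), Q.shape[1]


def _scan_core(y_r: np.ndarray, X_r: np.ndarray, df: int):
    """Simple-regression statistics of residualized phenotype on residualized dosages."""
    sxx = (X_r**2).sum(axis=0)
    syy = float((y_r**2).sum())
    sxy = X_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        resid_ss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(resid_ss / df / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = (sxx <= 1e-12) | (syy <= 1e-12)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.inf, se)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return beta, se, t, p


def nominal_scan(
    phenotype: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-variant OLS of the phenotype on dosage + covariates + intercept.

    Implemented by the Frisch-Waugh projection: phenotype and each dosage
    column are residualized against the covariates, then simple regression
    with residual degrees of freedom n - rank(covariates) - 2 (the t-test on
    the dosage coefficient is identical to the full OLS fit).
    """
    y = np.asarray(phenotype, dtype=float)
    X = np.atleast_2d(np.asarray(dosages, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, n_var = X.shape
    Q = _covariate_basis(covariates, n)
    y_r, n_z = _residualize(y, Q=Q)
    X_r, _ = _residualize(X, Q=Q)
    df = n - n_z - 1
    if df < 1:
        raise ValueError("not enough donors for the covariate count")
    beta, se, t, p = _scan_core(y_r, X_r, df)
    out = pd.DataFrame(
        {"variant": np.arange(n_var), "beta": beta, "se": se, "t_stat": t, "p_nominal": p}
    )
    if positions is not None:
        out["position"] = np.asarray(positions)
    return out


def empirical_peak_pvalue(
    phenotype: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None,
    n_permutations: int,
    seed: int | np.random.Generator = 0,
    *,
    Q: np.ndarray | None = None,
) -> tuple[int, float, pd.DataFrame]:
    """Peak-level empirical p-value by phenotype permutation.

    The observed statistic is the minimum nominal p over cis variants
    (equivalently the maximum absolute partial correlation, since all
    variants share the residual dof).  The covariate-residualized phenotype
    is permuted across donors (Freedman-Lane); p_emp =
    (1 + #{perm min-p <= observed}) / (B + 1).  Lead-variant ties break to
    the smallest index, i.e. the smallest genomic position for
    position-sorted input.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    X = np.atleast_2d(np.asarray(dosages, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    if Q is None:
        Q = _covariate_basis(covariates, n)
    y_r, n_z = _residualize(y, Q=Q)
    X_r, _ = _residualize(X, Q=Q)
    df = n - n_z - 1
    beta, se, t, p = _scan_core(y_r, X_r, df)
    lead = int(np.argmin(p))
    scan = pd.DataFrame(
        {"variant": np.arange(X.shape[1]), "beta": beta, "se": se, "t_stat": t, "p_nominal": p}
    )

    norms = np.sqrt((X_r**2).sum(axis=0))
    ok = norms > 1e-12
    if not ok.any() or float((y_r**2).sum()) <= 1e-12:
        return lead, 1.0, scan
    Xn = X_r[:, ok] / norms[ok]
    yn = y_r / np.sqrt((y_r**2).sum())
    obs = float(np.max(np.abs(Xn.T @ yn)))
    B = n_permutations
    # all permutations at once: argsort of an n x B uniform matrix
    perm_idx = np.argsort(rng.random((n, B)), axis=0)
    perm = y_r[perm_idx]
    # complete the Freedman-Lane cycle: the permuted residuals regain a
    # component in the covariate span, which must be projected out again or
    # permutation correlations are shrunk by ~sqrt(1 - k/n) and the test
    # becomes anti-conservative
    perm -= Q @ (Q.T @ perm)
    perm /= np.sqrt((perm**2).sum(axis=0, keepdims=True))
    perm_max = np.max(np.abs(Xn.T @ perm), axis=0)
    p_emp = (1.0 + np.sum(perm_max >= obs - 1e-12)) / (B + 1.0)
    return lead, float(p_emp), scan


def beta_approx_pvalue(
    perm_min_p: np.ndarray, observed_min_p: float
) -> tuple[float, tuple[float, float]]:
    """Beta approximation to the permutation null of the per-peak min p.

    Fits Beta(a, b) to the permutation minimum nominal p-values by moment
    matching and evaluates the observed minimum under the fitted CDF.  This
    gives continuous peak-level p-values below the 1/(B+1) floor of the
    direct estimator; the direct empirical estimator remains the reference.
    """
    x = np.clip(np.asarray(perm_min_p, dtype=float), 1e-300, 1.0)
    mean, var = x.mean(), x.var(ddof=1)
    if var <= 0:
        raise ValueError("degenerate permutation distribution")
    common = mean * (1.0 - mean) / var - 1.0
    a, b = max(mean * common, 1e-6), max((1.0 - mean) * common, 1e-6)
    return float(stats.beta.cdf(observed_min_p, a, b)), (a, b)


def storey_qvalues(
    p_values: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> tuple[np.ndarray, float]:
    """Storey q-values with the lambda-grid-median pi0 estimator.

    pi0(lambda) = #{p > lambda} / ((1 - lambda) m), clamped to (0, 1]; pi0
    is the median over the grid.  q_i = min over p_j >= p_i of
    pi0 * m * p_j / rank(p_j), monotone non-decreasing in p.  Forcing
    pi0 = 1 reproduces Benjamini-Hochberg exactly.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m < 10:
        raise ValueError("need at least 10 p-values")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid)
    if pi0 is None:
        pi0_lambda = np.array([(p > lam).sum() / ((1.0 - lam) * m) for lam in grid])
        pi0 = float(np.clip(np.median(np.minimum(pi0_lambda, 1.0)), np.finfo(float).tiny, 1.0))
    elif not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, pi0


# ---------------------------------------------------------------------------
# the mapping engine
# ---------------------------------------------------------------------------

def map_caqtls(
    donor_cpm: CpmMatrix,
    dosages: DosageMatrix,
    peaks: PeakSet,
    cfg: QtlConfig,
    *,
    extra_covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Map caQTLs for every peak: scan, permute, then Storey q-values.

    Donor order in ``donor_cpm`` columns and ``dosages`` rows must agree.
    Covariates are genotype PCs plus phenotype PCs (and any extras).  Peaks
    with no eligible cis variant are flagged untested (NaN p/q).
    """
    if donor_cpm.sample_ids != dosages.sample_ids:
        raise ValueError("donor order mismatch between phenotype and dosages")
    n_donors = len(donor_cpm.sample_ids)
    Y = _transform(donor_cpm.values.T, cfg.transform)  # donors x peaks

    covs = []
    if cfg.n_genotype_pcs > 0:
        G = np.nan_to_num(dosages.dosage, nan=0.0)
        covs.append(compute_pcs(G, cfg.n_genotype_pcs))
    k_pheno = min(cfg.phenotype_pcs_for(n_donors), n_donors - cfg.n_genotype_pcs - 3)
    if k_pheno > 0:
        covs.append(compute_pcs(Y, k_pheno, scale=True))
    if extra_covariates is not None:
        covs.append(np.atleast_2d(extra_covariates).reshape(n_donors, -1))
    C = np.column_stack(covs) if covs else None

    pos = np.asarray(dosages.positions)
    G_all = np.nan_to_num(dosages.dosage, nan=0.0)
    rng = stage_rng(cfg.seed, "qtl_permutations")
    Q = _covariate_basis(C, n_donors)
    records = []
    peak_index = {pid: i for i, pid in enumerate(donor_cpm.peak_ids)}
    for i, pid in enumerate(peaks.peak_ids):
        if pid not in peak_index:
            continue
        y = Y[:, peak_index[pid]]
        cis = select_cis_variants(int(peaks.starts[i]), int(peaks.ends[i]), dosages, cfg)
        if cis.size == 0:
            records.append(
                {
                    "peak_id": pid,
                    "lead_variant": None,
                    "lead_pos": np.nan,
                    "beta": np.nan,
                    "se": np.nan,
                    "p_nominal": np.nan,
                    "p_empirical": np.nan,
                    "n_variants": 0,
                    "distance": np.nan,
                }
            )
            continue
        X = G_all[:, cis]
        lead, p_emp, scan = empirical_peak_pvalue(y, X, C, cfg.n_permutations, rng, Q=Q)
        lead_site = int(cis[lead])
        records.append(
            {
                "peak_id": pid,
                "lead_variant": lead_site,
                "lead_pos": int(pos[lead_site]),
                "beta": float(scan.loc[lead, "beta"]),
                "se": float(scan.loc[lead, "se"]),
                "p_nominal": float(scan.loc[lead, "p_nominal"]),
                "p_empirical": p_emp,
                "n_variants": int(cis.size),
                "distance": int(pos[lead_site]) - int(peaks.midpoints[i]),
            }
        )
    result = pd.DataFrame(records)
    tested = result["p_empirical"].notna()
    if tested.sum() >= 10:
        q, pi0 = storey_qvalues(result.loc[tested, "p_empirical"].to_numpy(), cfg.lambda_grid)
        result.loc[tested, "q_value"] = q
        result.attrs["pi0"] = pi0
    else:
        result["q_value"] = np.nan
    result["significant"] = result["q_value"] <= cfg.fdr
    return result


def choose_phenotype_pcs(
    donor_cpm: CpmMatrix,
    dosages: DosageMatrix,
    peaks: PeakSet,
    cfg: QtlConfig,
    k_grid: list[int],
    subset: int = 200,
    gain_threshold: float = 0.05,
) -> int:
    """Elbow scan for the phenotype-PC covariate count.

    Maps caQTLs on a peak subset for each candidate k and returns the first
    k after which the relative gain in discoveries drops below
    ``gain_threshold`` (the elbow of the discoveries-vs-PCs curve).
    """
    from dataclasses import replace as _replace

    sub_ids = donor_cpm.peak_ids[:subset]
    keep = np.isin(peaks.peak_ids, sub_ids)
    sub_peaks = PeakSet(
        peaks.chrom, peaks.starts[keep], peaks.ends[keep],
        [p for p, k in zip(peaks.peak_ids, keep) if k],
    )
    rows = [donor_cpm.peak_ids.index(p) for p in sub_peaks.peak_ids]
    sub_cpm = CpmMatrix(donor_cpm.values[rows], sub_peaks.peak_ids, list(donor_cpm.sample_ids))
    counts = []
    for k in k_grid:
        res = map_caqtls(sub_cpm, dosages, sub_peaks, _replace(cfg, n_phenotype_pcs=k))
        counts.append(int(res["significant"].fillna(False).sum()))
    best = k_grid[0]
    for i in range(1, len(k_grid)):
        if counts[i] <= counts[i - 1] * (1.0 + gain_threshold):
            break
        best = k_grid[i]
    return best


def _transform(Y: np.ndarray, how: str) -> np.ndarray:
    if how == "log2cpm":
        return np.log2(Y + 1.0)
    if how == "rint":
        out = np.empty_like(Y, dtype=float)
        n = Y.shape[0]
        for j in range(Y.shape[1]):
            r = stats.rankdata(Y[:, j])
            out[:, j] = stats.norm.ppf((r - 0.5) / n)
        return out
    raise ValueError(f"unknown transform: {how}")


def benchmark_precision_recall(
    results_inferred: pd.DataFrame,
    results_truth: pd.DataFrame,
    alpha: float = 0.05,
    p_column: str = "p_empirical",
) -> dict[str, float]:
    """Precision/recall of inferred-genotype caQTLs against truth-genotype caQTLs.

    Significance on each side is Benjamini-Hochberg corrected peak-level
    p < alpha.  Precision is the fraction of inferred discoveries replicated
    by the truth-genotype analysis; recall is the fraction of truth-genotype
    discoveries recovered with inferred genotypes.
    """

    def significant(df: pd.DataFrame) -> set[str]:
        ok = df[p_column].notna()
        reject = multipletests(df.loc[ok, p_column], alpha=alpha, method="fdr_bh")[0]
        return set(df.loc[ok, "peak_id"].to_numpy()[reject])

    s_inf = significant(results_inferred)
    s_true = significant(results_truth)
    precision = len(s_inf & s_true) / len(s_inf) if s_inf else np.nan
    recall = len(s_true & s_inf) / len(s_true) if s_true else np.nan
    return {
        "precision": precision,
        "recall": recall,
        "n_inferred": len(s_inf),
        "n_truth": len(s_true),
    }
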