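"""Synthetic data with known ground truth for the full caQTL pipeline.

Generates every input the downstream stages need: a phased haplotype
reference panel with tunable linkage disequilibrium (copying-mosaic
process), diploid donors drawn from the panel with each donor contributing
one or more samples, sparse ATAC-like read pileups concentrated in peak
regions, negative-binomial peak counts with genotype-dependent means
(planted caQTLs), and paired association summary statistics with shared or
distinct causal variants for colocalization scenarios.

All generators are deterministic under a fixed master seed; per-stage
streams are derived from the master seed by stable name hashing, so adding
a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .peakcall import PeakCountMatrix, PeakSet
from .genotype import DosageMatrix, ReadPileup

__all__ = [
    "SimConfig",
    "HaplotypePanel",
    "SimTruth",
    "stage_rng",
    "simulate_panel",
    "simulate_peaks",
    "simulate_cohort",
    "plant_caqtl_effects",
    "simulate_reads",
    "simulate_bin_coverage",
    "simulate_summary_stats",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent random stream for a named pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


@dataclass
class SimConfig:
    """Simulation parameters; the defaults are the study conditions.

    Rates are per site (panel) or per base (reads).  ``peak_depth_mean`` and
    ``background_depth_mean`` are expected reads overlapping a single base
    inside / outside peaks.  ``nb_dispersion`` is the negative-binomial
    overdispersion alpha with variance mu + alpha * mu^2.
    """

    n_hap: int = 200
    n_sites: int = 2000
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    n_donors: int = 100
    dup_k_max: int = 3
    mosaic_switch_rate: float = 0.002
    mutation_rate: float = 0.01
    peak_depth_mean: float = 3.0
    background_depth_mean: float = 0.02
    seq_error: float = 0.01
    n_peaks: int = 500
    peak_length: int = 250
    sites_per_peak: int = 2
    frac_causal_peaks: float = 0.2
    effect_grid: tuple[float, ...] = (0.4, 0.6, 0.8)
    peak_count_baseline: float = 100.0
    nb_dispersion: float = 0.1
    n_founders: int | None = None  # default max(2, n_hap // 4)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mosaic_switch_rate", "mutation_rate", "seq_error", "frac_causal_peaks"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.peak_depth_mean <= 0 or self.background_depth_mean <= 0:
            raise ValueError("depth means must be positive")
        if self.n_hap < 4 or self.n_sites < 2:
            raise ValueError("panel needs n_hap >= 4 and n_sites >= 2")

    @property
    def founders(self) -> int:
        """Number of i.i.d. Bernoulli(1/2) founder haplotypes seeding the mosaic.

        A quarter of the panel by default: with too few founders the whole
        panel is one pedigree and even unrelated donors share most alleles
        identically by descent, destroying the bimodal same-donor/unrelated
        correlation structure donor deduplication depends on.
        """
        if self.n_founders is not None:
            return max(2, min(self.n_founders, self.n_hap))
        return max(2, self.n_hap // 4)


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes over ordered sites (0-based coordinates)."""

    chrom: str
    chrom_length: int
    site_positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    haplotypes: np.ndarray  # (n_hap, n_sites) in {0, 1}

    def __post_init__(self) -> None:
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if np.any(np.diff(self.site_positions) <= 0):
            raise ValueError("site positions must be strictly increasing")
        if self.haplotypes.shape[0] < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    @property
    def monomorphic(self) -> np.ndarray:
        """Flag for columns with no variation in the panel."""
        af = self.allele_freq
        return (af == 0.0) | (af == 1.0)

    @property
    def variant_ids(self) -> list[str]:
        return [f"{self.chrom}:{p + 1}" for p in self.site_positions]


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    donor_ids: list[str]
    sample_ids: list[str]
    sample_to_donor: dict[str, str]
    true_dosages: np.ndarray  # (n_donors, n_sites) in {0, 1, 2}
    causal_map: dict[str, tuple[int, float]] = field(default_factory=dict)
    null_peaks: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if set(self.sample_to_donor) != set(self.sample_ids):
            raise ValueError("every sample must map to exactly one donor")

    @property
    def sample_donor_index(self) -> np.ndarray:
        lookup = {d: i for i, d in enumerate(self.donor_ids)}
        return np.array([lookup[self.sample_to_donor[s]] for s in self.sample_ids])

    def sample_dosages(self) -> np.ndarray:
        return self.true_dosages[self.sample_donor_index]

    def dosage_matrix(self, positions: np.ndarray, per_sample: bool = False) -> DosageMatrix:
        if per_sample:
            return DosageMatrix(list(self.sample_ids), positions, self.sample_dosages().astype(float))
        return DosageMatrix(list(self.donor_ids), positions, self.true_dosages.astype(float))


# ---------------------------------------------------------------------------
# panel and cohort
# ---------------------------------------------------------------------------

def _mosaic_copy(
    templates: np.ndarray,
    switch_rate: float,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy one mosaic haplotype from a pool of templates.

    Starts from a uniformly chosen template and switches to a uniformly
    chosen one with probability ``switch_rate`` at each site; each copied
    allele flips with probability ``mutation_rate``.
    """
    n_templates, n_sites = templates.shape
    switches = rng.random(n_sites) < switch_rate
    switches[0] = True  # initial template choice
    n_seg = int(switches.sum())
    choices = rng.integers(0, n_templates, size=n_seg)
    template_idx = np.repeat(choices, np.diff(np.append(np.flatnonzero(switches), n_sites)))
    hap = templates[template_idx, np.arange(n_sites)].copy()
    flips = rng.random(n_sites) < mutation_rate
    hap[flips] = 1 - hap[flips]
    return hap


def simulate_panel(cfg: SimConfig, peaks: PeakSet | None = None) -> HaplotypePanel:
    """Simulate a phased reference panel with LD via a copying-mosaic process.

    The first ``cfg.founders`` haplotypes are i.i.d. Bernoulli(1/2); each
    later haplotype copies previously generated ones, switching template
    with probability ``mosaic_switch_rate`` per site and flipping alleles
    with probability ``mutation_rate``, so nearby sites are correlated
    while founder diversity keeps unrelated genomes distinguishable.

    When ``peaks`` is given, ``sites_per_peak`` site positions are placed
    inside every peak and the rest uniformly outside, guaranteeing each peak
    carries typed variants (ATAC reads only cover peaks, so in-peak variants
    are the directly observable ones).
    """
    rng = stage_rng(cfg.seed, "panel")
    positions = _site_positions(cfg, peaks, rng)
    haps = np.empty((cfg.n_hap, cfg.n_sites), dtype=np.int8)
    k = cfg.founders
    haps[:k] = rng.integers(0, 2, (k, cfg.n_sites))
    for h in range(k, cfg.n_hap):
        haps[h] = _mosaic_copy(haps[:h], cfg.mosaic_switch_rate, cfg.mutation_rate, rng)
    ref = np.full(cfg.n_sites, "A")
    alt = np.full(cfg.n_sites, "G")
    return HaplotypePanel(cfg.chrom, cfg.chrom_length, positions, ref, alt, haps)


def _site_positions(cfg: SimConfig, peaks: PeakSet | None, rng: np.random.Generator) -> np.ndarray:
    if peaks is None:
        pos = rng.choice(cfg.chrom_length, size=cfg.n_sites, replace=False)
        return np.sort(pos)
    in_peak = []
    for s, e in zip(peaks.starts, peaks.ends):
        width = e - s
        k = min(cfg.sites_per_peak, width)
        in_peak.append(s + rng.choice(width, size=k, replace=False))
    in_peak = np.concatenate(in_peak) if in_peak else np.array([], dtype=np.int64)
    n_bg = cfg.n_sites - in_peak.size
    if n_bg < 0:
        raise ValueError("n_sites too small for sites_per_peak * n_peaks")
    taken = set(in_peak.tolist())
    bg = []
    while len(bg) < n_bg:
        cand = int(rng.integers(0, cfg.chrom_length))
        if cand not in taken:
            bg.append(cand)
            taken.add(cand)
    return np.sort(np.concatenate([in_peak, np.array(bg, dtype=np.int64)]))


def simulate_peaks(cfg: SimConfig) -> PeakSet:
    """Place non-overlapping peaks of ``peak_length`` bp evenly spaced with jitter."""
    rng = stage_rng(cfg.seed, "peaks")
    spacing = cfg.chrom_length // cfg.n_peaks
    if spacing <= cfg.peak_length:
        raise ValueError("chromosome too short for the requested peaks")
    jitter = rng.integers(0, spacing - cfg.peak_length, size=cfg.n_peaks)
    starts = np.arange(cfg.n_peaks) * spacing + jitter
    ends = starts + cfg.peak_length
    if ends[-1] > cfg.chrom_length:
        raise ValueError("peak outside chromosome bounds")
    return PeakSet(cfg.chrom, starts, ends, [f"peak_{i}" for i in range(cfg.n_peaks)])


def simulate_cohort(panel: HaplotypePanel, cfg: SimConfig) -> SimTruth:
    """Draw diploid donors from the panel and assign 1..dup_k_max samples each.

    Each donor genome is two mosaic recombinants of panel haplotypes (same
    switch/mutation process as the panel itself); the dosage is the allele
    sum of the two.
    """
    if cfg.n_donors < 2:
        raise ValueError("need at least 2 donors")
    rng = stage_rng(cfg.seed, "cohort")
    dosages = np.empty((cfg.n_donors, panel.n_sites), dtype=np.int8)
    for d in range(cfg.n_donors):
        h1 = _mosaic_copy(panel.haplotypes, cfg.mosaic_switch_rate, cfg.mutation_rate, rng)
        h2 = _mosaic_copy(panel.haplotypes, cfg.mosaic_switch_rate, cfg.mutation_rate, rng)
        dosages[d] = h1 + h2
    donor_ids = [f"donor_{d:04d}" for d in range(cfg.n_donors)]
    n_per = rng.integers(1, cfg.dup_k_max + 1, size=cfg.n_donors)
    sample_ids, mapping = [], {}
    for d, k in zip(donor_ids, n_per):
        for j in range(k):
            sid = f"{d}_s{j}"
            sample_ids.append(sid)
            mapping[sid] = d
    return SimTruth(donor_ids, sample_ids, mapping, dosages)


# ---------------------------------------------------------------------------
# planted effects and reads
# ---------------------------------------------------------------------------

def plant_caqtl_effects(
    truth: SimTruth,
    peaks: PeakSet,
    panel: HaplotypePanel,
    cfg: SimConfig,
    *,
    max_causal_distance: int = 0,
    maf_min: float = 0.05,
) -> SimTruth:
    """Assign causal variants and multiplicative log effects to peaks.

    A fraction ``frac_causal_peaks`` of peaks receives a causal variant with
    cohort MAF > ``maf_min`` located within the peak (default) or within
    ``max_causal_distance`` bp of its boundaries, with a log effect drawn
    from ``effect_grid``; remaining peaks are null.  Peaks with no eligible
    variant stay null.
    """
    rng = stage_rng(cfg.seed, "effects")
    af = truth.true_dosages.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    pos = panel.site_positions
    n_causal = int(round(cfg.frac_causal_peaks * len(peaks)))
    order = rng.permutation(len(peaks))
    causal_map: dict[str, tuple[int, float]] = {}
    for pi in order:
        if len(causal_map) >= n_causal:
            break
        lo = peaks.starts[pi] - max_causal_distance
        hi = peaks.ends[pi] + max_causal_distance
        eligible = np.flatnonzero((pos >= lo) & (pos < hi) & (maf > maf_min))
        if max_causal_distance > 0:
            # exclude in-peak (read-covered) variants so only imputation can
            # recover the causal genotype in the wide-window scenario
            in_any_peak = _in_peaks(pos[eligible], peaks)
            eligible = eligible[~in_any_peak]
        if eligible.size == 0:
            continue
        v = int(rng.choice(eligible))
        beta = float(rng.choice(cfg.effect_grid))
        causal_map[peaks.peak_ids[pi]] = (v, beta)
    null_peaks = set(peaks.peak_ids) - set(causal_map)
    return replace(truth, causal_map=causal_map, null_peaks=null_peaks)


def _in_peaks(pos: np.ndarray, peaks: PeakSet) -> np.ndarray:
    lo = np.searchsorted(peaks.starts, pos, side="right") - 1
    ok = lo >= 0
    res = np.zeros(pos.shape, dtype=bool)
    res[ok] = pos[ok] < peaks.ends[lo[ok]]
    return res


def simulate_reads(
    truth: SimTruth,
    peaks: PeakSet,
    cfg: SimConfig,
    panel: HaplotypePanel,
) -> tuple[ReadPileup, PeakCountMatrix]:
    """Simulate per-site pileups and genotype-dependent peak counts.

    Site depth is Poisson with mean ``peak_depth_mean`` inside peaks and
    ``background_depth_mean`` elsewhere.  Each read reports the allele of a
    uniformly chosen donor haplotype, flipped with probability ``seq_error``,
    so alt reads are Binomial(depth, (g/2)(1-eps) + (1-g/2)eps).

    Peak counts are negative binomial with mean
    ``baseline_p * exp(g_causal * effect)`` shared across all samples of a
    donor (same genotype) but drawn independently per sample.
    """
    pos = panel.site_positions
    if len(peaks) and (peaks.starts.min() < 0 or peaks.ends.max() > panel.chrom_length):
        raise ValueError("peak outside chromosome bounds")
    rng = stage_rng(cfg.seed, "reads")
    in_peak = _in_peaks(pos, peaks)
    depth_mean = np.where(in_peak, cfg.peak_depth_mean, cfg.background_depth_mean)

    sample_dos = truth.sample_dosages()  # (n_samples, n_sites)
    n_samples, n_sites = sample_dos.shape
    depth = rng.poisson(np.broadcast_to(depth_mean, (n_samples, n_sites)))
    eps = cfg.seq_error
    p_alt = (sample_dos / 2.0) * (1 - eps) + (1 - sample_dos / 2.0) * eps
    alt = rng.binomial(depth, p_alt)
    pileup = ReadPileup(list(truth.sample_ids), pos, depth - alt, alt)

    counts = _simulate_counts(truth, peaks, cfg, stage_rng(cfg.seed, "counts"))
    return pileup, counts


def _simulate_counts(
    truth: SimTruth, peaks: PeakSet, cfg: SimConfig, rng: np.random.Generator
) -> PeakCountMatrix:
    n_samples = len(truth.sample_ids)
    donor_idx = truth.sample_donor_index
    baselines = cfg.peak_count_baseline * np.exp(rng.normal(0.0, 0.5, size=len(peaks)))
    mu = np.tile(baselines[:, None], (1, n_samples))
    for pid, (v, beta) in truth.causal_map.items():
        pi = peaks.peak_ids.index(pid)
        g = truth.true_dosages[donor_idx, v]
        mu[pi] = baselines[pi] * np.exp(g * beta)
    alpha = cfg.nb_dispersion
    if alpha > 0:
        lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    else:
        lam = mu
    counts = rng.poisson(lam)
    return PeakCountMatrix(counts, list(peaks.peak_ids), list(truth.sample_ids))


def simulate_bin_coverage(
    peaks: PeakSet,
    cfg: SimConfig,
    n_samples: int,
    *,
    bin_size: int = 50,
    seed_stage: str = "bincov",
) -> np.ndarray:
    """Per-bin read counts for joint peak calling (bins x samples).

    Bins overlapping a peak draw Poisson counts at the in-peak rate, others
    at the background rate, consistent with the site-level read model.
    """
    rng = stage_rng(cfg.seed, seed_stage)
    n_bins = cfg.chrom_length // bin_size
    starts = np.arange(n_bins) * bin_size
    rate = np.full(n_bins, cfg.background_depth_mean * bin_size)
    for s, e in zip(peaks.starts, peaks.ends):
        b0, b1 = s // bin_size, (e - 1) // bin_size + 1
        rate[b0:b1] = cfg.peak_depth_mean * bin_size
    return rng.poisson(np.broadcast_to(rate[:, None], (n_bins, n_samples)))


# ---------------------------------------------------------------------------
# summary statistics for colocalization
# ---------------------------------------------------------------------------

def simulate_summary_stats(
    truth: SimTruth,
    variant_indices: np.ndarray,
    scenario: str,
    n_eff: int,
    cfg: SimConfig,
    *,
    beta_causal: float = 0.3,
    seed_stage: str = "sumstats",
):
    """Paired association summary statistics over one locus.

    ``scenario`` is one of ``shared`` (one causal variant drives both
    traits), ``distinct`` (two causal variants with r^2 < 0.2), or
    ``one_null`` (trait 2 has no signal).  Marginal effects follow the LD
    with the causal variant (beta_v = beta_c * cov(g_v, g_c) / var(g_v));
    estimates are Normal(beta_v, SE^2) with SE = 1/sqrt(2 n AF (1-AF)).
    """
    from .colocal import SummaryStatSet

    if scenario not in ("shared", "distinct", "one_null"):
        raise ValueError(f"unknown scenario: {scenario}")
    variant_indices = np.asarray(variant_indices)
    G = truth.true_dosages[:, variant_indices].astype(float)
    af = G.mean(axis=0) / 2.0
    poly = (af > 0) & (af < 1)
    if scenario == "distinct" and variant_indices.size < 2:
        raise ValueError("scenario 'distinct' needs at least 2 variants")

    rng = stage_rng(cfg.seed, seed_stage)
    var = G.var(axis=0)
    var[var == 0] = np.nan

    def marginal(causal: int) -> np.ndarray:
        cov = ((G - G.mean(axis=0)) * (G[:, [causal]] - G[:, causal].mean())).mean(axis=0)
        return np.nan_to_num(beta_causal * cov / var)

    poly_idx = np.flatnonzero(poly)
    c1 = int(rng.choice(poly_idx))
    if scenario == "shared":
        b1, b2 = marginal(c1), marginal(c1)
    elif scenario == "one_null":
        b1, b2 = marginal(c1), np.zeros(variant_indices.size)
    else:
        corr = np.corrcoef(G[:, poly_idx].T)
        r2 = corr[np.searchsorted(poly_idx, c1)] ** 2
        low_ld = poly_idx[r2 < 0.2]
        if low_ld.size == 0:
            raise ValueError("no second causal variant with r^2 < 0.2 available")
        c2 = int(rng.choice(low_ld))
        b1, b2 = marginal(c1), marginal(c2)

    af_safe = np.clip(af, 1e-3, 1 - 1e-3)
    se = 1.0 / np.sqrt(2.0 * n_eff * af_safe * (1.0 - af_safe))
    beta_hat1 = rng.normal(b1, se)
    beta_hat2 = rng.normal(b2, se)
    ids = [f"v{int(i)}" for i in variant_indices]
    mk = lambda bh: SummaryStatSet(
        variant_ids=ids,
        beta=bh,
        se=se.copy(),
        af=af.copy(),
        n=np.full(len(ids), n_eff),
        trait_type="quantitative",
        locus_id=f"locus_{scenario}",
    )
    return mk(beta_hat1), mk(beta_hat2)
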