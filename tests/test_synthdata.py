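"""Generator contracts: determinism, LD structure, read and effect models."""

import numpy as np
import pytest
from scipy import stats

from ataqtl.synthdata import (
    SimConfig,
    plant_caqtl_effects,
    simulate_cohort,
    simulate_panel,
    simulate_peaks,
    simulate_reads,
    simulate_summary_stats,
)


def _r2(a, b):
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return np.corrcoef(a, b)[0, 1] ** 2


class TestPanel:
    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(n_hap=20, n_sites=150, seed=5)
        p1, p2 = simulate_panel(cfg), simulate_panel(cfg)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert np.array_equal(p1.site_positions, p2.site_positions)

    def test_zero_rates_force_exact_template_copies(self):
        cfg = SimConfig(n_hap=6, n_sites=80, mosaic_switch_rate=0.0, mutation_rate=0.0, seed=2)
        panel = simulate_panel(cfg)
        H = panel.haplotypes
        for h in range(2, 6):
            assert any(np.array_equal(H[h], H[t]) for t in range(h)), h

    def test_ld_decays_with_distance(self):
        cfg = SimConfig(n_hap=80, n_sites=2000, mosaic_switch_rate=0.002, seed=3)
        H = simulate_panel(cfg).haplotypes.astype(float)
        adj = [_r2(H[:, m], H[:, m + 1]) for m in range(0, 1800, 7)]
        far = [_r2(H[:, m], H[:, m + 100]) for m in range(0, 1800, 7)]
        assert np.nanmean(adj) > np.nanmean(far)

    def test_monomorphic_columns_flagged(self):
        cfg = SimConfig(n_hap=10, n_sites=50, seed=1)
        panel = simulate_panel(cfg)
        af = panel.haplotypes.mean(axis=0)
        assert np.array_equal(panel.monomorphic, (af == 0) | (af == 1))

    def test_bad_dimensions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_hap=2, n_sites=100)
        with pytest.raises(ValueError):
            SimConfig(n_hap=10, n_sites=1)


class TestCohort:
    def test_one_sample_per_donor_when_dup_k_is_one(self):
        cfg = SimConfig(n_hap=16, n_sites=100, n_donors=12, dup_k_max=1, seed=4)
        truth = simulate_cohort(simulate_panel(cfg), cfg)
        assert len(truth.sample_ids) == 12

    def test_every_donor_has_at_least_one_sample(self):
        cfg = SimConfig(n_hap=16, n_sites=60, n_donors=40, dup_k_max=7, seed=4)
        truth = simulate_cohort(simulate_panel(cfg), cfg)
        assert len(truth.sample_ids) >= 40
        assert set(truth.sample_to_donor.values()) == set(truth.donor_ids)

    def test_zero_switch_dosage_is_sum_of_two_panel_haplotypes(self):
        cfg = SimConfig(
            n_hap=10, n_sites=60, n_donors=6, mosaic_switch_rate=0.0, mutation_rate=0.0, seed=9
        )
        panel = simulate_panel(cfg)
        truth = simulate_cohort(panel, cfg)
        H = panel.haplotypes
        sums = {tuple(H[i] + H[j]) for i in range(10) for j in range(10)}
        for d in range(6):
            assert tuple(truth.true_dosages[d]) in sums

    def test_cohort_af_tracks_panel_af(self):
        cfg = SimConfig(n_hap=100, n_sites=300, n_donors=500, dup_k_max=1, seed=6)
        panel = simulate_panel(cfg)
        truth = simulate_cohort(panel, cfg)
        panel_af = panel.allele_freq
        cohort_af = truth.true_dosages.mean(axis=0) / 2
        mid = (panel_af >= 0.1) & (panel_af <= 0.9)
        assert np.abs(cohort_af[mid] - panel_af[mid]).max() < 0.05

    def test_too_few_donors_rejected(self):
        cfg = SimConfig(n_hap=8, n_sites=50, n_donors=1)
        with pytest.raises(ValueError):
            simulate_cohort(simulate_panel(cfg), cfg)


class TestReads:
    def test_error_free_hom_ref_site_gives_pure_ref_pileup(self, tiny_cfg):
        cfg = SimConfig(
            n_hap=12, n_sites=80, n_donors=5, dup_k_max=1, n_peaks=4, chrom_length=20_000,
            peak_length=1000, peak_depth_mean=5.0, seq_error=1e-12, seed=8,
        )
        peaks = simulate_peaks(cfg)
        panel = simulate_panel(cfg, peaks)
        truth = simulate_cohort(panel, cfg)
        pileup, _ = simulate_reads(truth, peaks, cfg, panel)
        dos = truth.sample_dosages()
        hom_ref = dos == 0
        assert pileup.alt_counts[hom_ref].sum() == 0
        hom_alt = dos == 2
        assert pileup.ref_counts[hom_alt].sum() == 0

    def test_het_alt_fraction_near_half_at_high_depth(self):
        cfg = SimConfig(
            n_hap=8, n_sites=10, n_donors=4, dup_k_max=1, n_peaks=1, chrom_length=5000,
            peak_length=4000, peak_depth_mean=10_000.0, seq_error=1e-12, seed=10,
        )
        peaks = simulate_peaks(cfg)
        panel = simulate_panel(cfg, peaks)
        truth = simulate_cohort(panel, cfg)
        pileup, _ = simulate_reads(truth, peaks, cfg, panel)
        het = (truth.sample_dosages() == 1) & (pileup.depth > 0)
        depth = pileup.depth[het]
        frac = pileup.alt_counts[het] / depth
        # binomial 99.9% CI at depth ~10,000
        assert np.all(np.abs(frac - 0.5) < 3.3 * np.sqrt(0.25 / depth))

    def test_effective_coverage_monotone_in_peak_depth(self):
        covs = []
        for depth in (0.5, 2.0, 8.0):
            cfg = SimConfig(
                n_hap=12, n_sites=200, n_donors=4, dup_k_max=1, n_peaks=20,
                chrom_length=100_000, peak_length=1500, peak_depth_mean=depth,
                background_depth_mean=0.01, seed=12,
            )
            peaks = simulate_peaks(cfg)
            panel = simulate_panel(cfg)
            truth = simulate_cohort(panel, cfg)
            pileup, _ = simulate_reads(truth, peaks, cfg, panel)
            covs.append((pileup.depth >= 1).mean())
        assert covs[0] < covs[1] < covs[2]

    def test_peak_outside_chromosome_rejected(self, tiny_world):
        from ataqtl.peakcall import PeakSet

        cfg, panel, truth = tiny_world["cfg"], tiny_world["panel"], tiny_world["truth"]
        bad = PeakSet(cfg.chrom, np.array([cfg.chrom_length - 10]), np.array([cfg.chrom_length + 500]))
        with pytest.raises(ValueError):
            simulate_reads(truth, bad, cfg, panel)


class TestPlantedEffects:
    def test_causal_variants_lie_inside_their_peaks(self, tiny_world):
        peaks, truth, panel = tiny_world["peaks"], tiny_world["truth"], tiny_world["panel"]
        pid_to_idx = {p: i for i, p in enumerate(peaks.peak_ids)}
        for pid, (v, beta) in truth.causal_map.items():
            i = pid_to_idx[pid]
            pos = panel.site_positions[v]
            assert peaks.starts[i] <= pos < peaks.ends[i]
            assert beta in tiny_world["cfg"].effect_grid

    def test_null_peaks_complement_causal_map(self, tiny_world):
        truth, peaks = tiny_world["truth"], tiny_world["peaks"]
        assert truth.null_peaks | set(truth.causal_map) == set(peaks.peak_ids)
        assert not truth.null_peaks & set(truth.causal_map)

    def test_distal_mode_places_causals_outside_peaks(self):
        cfg = SimConfig(
            n_hap=40, n_sites=400, n_donors=30, dup_k_max=1, n_peaks=30,
            chrom_length=300_000, sites_per_peak=2, seed=13,
        )
        peaks = simulate_peaks(cfg)
        panel = simulate_panel(cfg, peaks)
        truth = simulate_cohort(panel, cfg)
        truth = plant_caqtl_effects(truth, peaks, panel, cfg, max_causal_distance=50_000)
        from ataqtl.synthdata import _in_peaks

        for pid, (v, _) in truth.causal_map.items():
            assert not _in_peaks(panel.site_positions[[v]], peaks)[0]


@pytest.fixture(scope="module")
def cohort():
    cfg = SimConfig(n_hap=60, n_sites=300, n_donors=400, dup_k_max=1, seed=21)
    panel = simulate_panel(cfg)
    return cfg, simulate_cohort(panel, cfg)


class TestSummaryStats:
    def test_same_seed_gives_identical_statistics(self, cohort):
        cfg, truth = cohort
        idx = np.arange(40)
        a1, b1 = simulate_summary_stats(truth, idx, "shared", 5000, cfg)
        a2, b2 = simulate_summary_stats(truth, idx, "shared", 5000, cfg)
        assert np.array_equal(a1.beta, a2.beta) and np.array_equal(b1.beta, b2.beta)

    def test_shared_scenario_lead_agrees_at_large_n(self, cohort):
        cfg, truth = cohort
        idx = np.arange(40)
        s1, s2 = simulate_summary_stats(truth, idx, "shared", 10_000_000, cfg)
        assert np.argmax(np.abs(s1.z)) == np.argmax(np.abs(s2.z))

    def test_one_null_z_scores_are_standard_normal(self, cohort):
        cfg, truth = cohort
        zs = []
        for k in range(40):
            _, s2 = simulate_summary_stats(
                truth, np.arange(50), "one_null", 5000, cfg, seed_stage=f"null{k}"
            )
            zs.append(s2.z)
        z = np.concatenate(zs)
        # half-normal mean sqrt(2/pi) ~ 0.7979
        assert abs(np.mean(np.abs(z)) - 0.7979) < 3 * np.std(np.abs(z)) / np.sqrt(z.size)

    def test_distinct_scenario_requires_two_variants(self, cohort):
        cfg, truth = cohort
        with pytest.raises(ValueError):
            simulate_summary_stats(truth, np.array([3]), "distinct", 1000, cfg)
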