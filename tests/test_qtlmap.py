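"""caQTL scan mechanics: cis selection, OLS, permutations, q-values."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ataqtl.genotype import DosageMatrix
from ataqtl.qtlmap import (
    QtlConfig,
    beta_approx_pvalue,
    benchmark_precision_recall,
    compute_pcs,
    empirical_peak_pvalue,
    nominal_scan,
    select_cis_variants,
    storey_qvalues,
)


def _dosages(rng, n=30, m=40, positions=None):
    pos = np.arange(m) * 1000 if positions is None else positions
    G = rng.binomial(2, 0.3, (n, m)).astype(float)
    return DosageMatrix([f"d{i}" for i in range(n)], pos, G)


class TestSelectCis:
    def test_window_is_half_open(self, rng):
        pos = np.array([0, 10_000, 20_000, 40_000, 50_000])
        G = rng.binomial(2, 0.5, (40, 5)).astype(float)
        dm = DosageMatrix([f"d{i}" for i in range(40)], pos, G)
        cfg = QtlConfig(cis_window=10_000)
        # peak [20_000, 30_000): window [10_000, 40_000)
        sel = select_cis_variants(20_000, 30_000, dm, cfg)
        assert 1 in sel and 2 in sel and 3 not in sel and 0 not in sel

    def test_maf_threshold_is_strict(self):
        n = 40
        G = np.zeros((n, 2))
        G[: int(0.05 * 2 * n) // 2 * 2, 0] = 1  # AF exactly 0.05
        G[:6, 1] = 1  # AF 0.075
        G[np.arange(n) % 2 == 0, 1] += 0  # keep
        dm = DosageMatrix([f"d{i}" for i in range(n)], np.array([100, 200]), G)
        sel = select_cis_variants(0, 1000, dm, QtlConfig(maf_min=0.05))
        assert 0 not in sel and 1 in sel

    def test_monomorphic_excluded(self, rng):
        G = np.column_stack([np.zeros(30), rng.binomial(2, 0.4, 30)])
        dm = DosageMatrix([f"d{i}" for i in range(30)], np.array([10, 20]), G)
        sel = select_cis_variants(0, 1000, dm, QtlConfig())
        assert 0 not in sel


class TestComputePcs:
    def test_collinear_data_loads_on_first_component(self, rng):
        t = rng.normal(size=50)
        X = np.column_stack([t, 2 * t])
        scores = compute_pcs(X, 1)
        assert np.corrcoef(scores[:, 0], t)[0, 1] ** 2 == pytest.approx(1.0)

    def test_scores_are_orthogonal(self, rng):
        X = rng.normal(size=(40, 10))
        S = compute_pcs(X, 4)
        G = S.T @ S
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_population_structure_separates_on_pc1(self):
        from ataqtl.synthdata import SimConfig, simulate_cohort, simulate_panel

        cfg_a = SimConfig(n_hap=40, n_sites=400, n_donors=25, dup_k_max=1, seed=31)
        cfg_b = SimConfig(n_hap=40, n_sites=400, n_donors=25, dup_k_max=1, seed=32)
        da = simulate_cohort(simulate_panel(cfg_a), cfg_a).true_dosages
        db = simulate_cohort(simulate_panel(cfg_b), cfg_b).true_dosages
        pc1 = compute_pcs(np.vstack([da, db]).astype(float), 1)[:, 0]
        assert (pc1[:25].mean() < pc1[25:].mean()) != (pc1[:25].max() >= pc1[25:].min()) or (
            pc1[:25].max() < pc1[25:].min() or pc1[25:].max() < pc1[:25].min()
        )

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            compute_pcs(rng.normal(size=(5, 3)), 3)


class TestNominalScan:
    def test_perfect_linear_fit(self, rng):
        g = rng.binomial(2, 0.4, 50).astype(float)
        scan = nominal_scan(2.0 * g, g[:, None])
        assert scan.loc[0, "beta"] == pytest.approx(2.0)
        assert scan.loc[0, "p_nominal"] <= np.finfo(float).tiny * 10

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        n = 20
        y = rng.normal(size=n)
        X = rng.binomial(2, 0.3, (n, 6)).astype(float)
        C = rng.normal(size=(n, 2))
        scan = nominal_scan(y, X, C)
        for j in range(6):
            design = sm.add_constant(np.column_stack([X[:, j], C]))
            fit = sm.OLS(y, design).fit()
            assert scan.loc[j, "beta"] == pytest.approx(fit.params[1], abs=1e-8)
            assert scan.loc[j, "se"] == pytest.approx(fit.bse[1], abs=1e-8)
            assert scan.loc[j, "p_nominal"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_null_pvalues_uniform(self, rng):
        n = 40
        ps = []
        for _ in range(2000):
            y = rng.normal(size=n)
            g = rng.binomial(2, 0.4, n).astype(float)
            ps.append(nominal_scan(y, g[:, None]).loc[0, "p_nominal"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        n = 60
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.5 * g + rng.normal(size=n)
        c = rng.normal(size=n)
        gc = g - g.mean()
        yc = y - y.mean()
        # orthogonalize c against span{1, g, y} jointly
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), gc, yc]))
        c = c - Q @ (Q.T @ c)
        b0 = nominal_scan(y, g[:, None]).loc[0, "beta"]
        b1 = nominal_scan(y, g[:, None], c[:, None]).loc[0, "beta"]
        assert b1 == pytest.approx(b0, abs=1e-10)

    def test_constant_phenotype_gives_p_one(self, rng):
        g = rng.binomial(2, 0.4, 30).astype(float)
        scan = nominal_scan(np.full(30, 3.0), g[:, None])
        assert scan.loc[0, "p_nominal"] == 1.0


class TestEmpiricalPvalue:
    def test_floor_is_one_over_b_plus_one(self, rng):
        n = 40
        g = rng.binomial(2, 0.5, n).astype(float)
        y = 3.0 * g + rng.normal(0, 0.05, n)
        lead, p, _ = empirical_peak_pvalue(y, g[:, None], None, 99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_null_empirical_pvalues_uniform(self, rng):
        n = 30
        ps = []
        for k in range(300):
            y = rng.normal(size=n)
            X = rng.binomial(2, 0.3, (n, 5)).astype(float)
            _, p, _ = empirical_peak_pvalue(y, X, None, 99, seed=k)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_duplicated_variant_columns_change_nothing(self, rng):
        n = 50
        X = rng.binomial(2, 0.4, (n, 4)).astype(float)
        y = X[:, 1] + rng.normal(0, 0.5, n)
        _, p1, _ = empirical_peak_pvalue(y, X, None, 200, seed=3)
        _, p2, _ = empirical_peak_pvalue(y, np.column_stack([X, X]), None, 200, seed=3)
        assert p1 == p2

    def test_beta_approximation_recovers_the_null_law(self, rng):
        perm_min_p = rng.beta(1.0, 8.0, 5000)
        p_beta, (a, b) = beta_approx_pvalue(perm_min_p, 0.01)
        assert p_beta == pytest.approx(stats.beta.cdf(0.01, 1.0, 8.0), abs=0.02)
        assert a == pytest.approx(1.0, abs=0.15) and b == pytest.approx(8.0, abs=1.2)


class TestStoreyQvalues:
    def test_pi0_hand_count_on_even_spread(self):
        p = np.arange(0.05, 1.0, 0.1)
        _, pi0 = storey_qvalues(p, lambda_grid=np.array([0.5]))
        assert pi0 == pytest.approx(1.0)

    def test_all_tiny_pvalues_have_tiny_q(self):
        q, pi0 = storey_qvalues(np.full(100, 0.001))
        assert np.all(q <= 0.001)

    def test_reduces_to_bh_when_pi0_forced_to_one(self, rng):
        p = rng.random(200)
        q, _ = storey_qvalues(p, pi0=1.0)
        _, q_bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_bh, atol=1e-12)

    def test_q_monotone_in_p(self, rng):
        p = rng.random(150)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestBenchmark:
    def _res(self, pvals):
        return pd.DataFrame({"peak_id": [f"p{i}" for i in range(len(pvals))], "p_empirical": pvals})

    def test_identical_sets_are_perfect(self):
        r = self._res([0.001] * 5 + [0.9] * 5)
        out = benchmark_precision_recall(r, r)
        assert out["precision"] == 1.0 and out["recall"] == 1.0

    def test_disjoint_sets_are_zero(self):
        a = self._res([0.0001] * 3 + [0.9] * 17)
        b = self._res([0.9] * 3 + [0.9] * 14 + [0.0001] * 3)
        out = benchmark_precision_recall(a, b)
        assert out["precision"] == 0.0 and out["recall"] == 0.0

    def test_partial_overlap_set_arithmetic(self):
        # truth-significant {p0..p3}, inferred-significant {p0, p1, p4}
        truth = self._res([1e-6, 1e-6, 1e-6, 1e-6] + [0.99] * 16)
        inf = self._res([1e-6, 1e-6, 0.99, 0.99, 1e-6] + [0.99] * 15)
        out = benchmark_precision_recall(inf, truth)
        assert out["precision"] == pytest.approx(2 / 3)
        assert out["recall"] == pytest.approx(1 / 2)

    def test_empty_inferred_set_is_undefined(self):
        out = benchmark_precision_recall(self._res([0.9] * 20), self._res([1e-6] * 20))
        assert np.isnan(out["precision"])
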