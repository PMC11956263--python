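"""Genotype likelihoods, Li-Stephens imputation, combiner, concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ataqtl.genotype import (
    DosageMatrix,
    GenotypeLikelihoods,
    ImputationParams,
    ReadPileup,
    direct_call,
    effective_coverage,
    genotype_concordance,
    impute,
    impute_brute_force,
    pileup_likelihoods,
    train_combiner,
)
from ataqtl.synthdata import HaplotypePanel


def _pileup(ref, alt):
    ref = np.atleast_2d(ref)
    alt = np.atleast_2d(alt)
    pos = np.arange(ref.shape[1]) * 10
    return ReadPileup([f"s{i}" for i in range(ref.shape[0])], pos, ref, alt)


def _panel(H, length=10_000):
    H = np.asarray(H, dtype=np.int8)
    pos = np.arange(H.shape[1]) * 10
    return HaplotypePanel("chr1", length, pos, np.full(H.shape[1], "A"), np.full(H.shape[1], "G"), H)


class TestPileupLikelihoods:
    def test_binomial_triplet_hand_values(self):
        gl = pileup_likelihoods(_pileup([[3]], [[0]]), eps=0.01)
        np.testing.assert_allclose(gl.likelihoods[0, 0], [0.970299, 0.125, 1e-6], rtol=1e-9)

    def test_unobserved_site_is_flat(self):
        gl = pileup_likelihoods(_pileup([[0]], [[0]]), eps=0.01)
        assert np.array_equal(gl.likelihoods[0, 0], [1.0, 1.0, 1.0])
        assert not gl.mask[0, 0]

    def test_one_ref_one_alt_at_tiny_error(self):
        gl = pileup_likelihoods(_pileup([[1]], [[1]]), eps=1e-9)
        L = gl.likelihoods[0, 0]
        assert L[1] == pytest.approx(0.5)
        assert L[0] < 1e-8 and L[2] < 1e-8

    def test_eps_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pileup_likelihoods(_pileup([[1]], [[0]]), eps=0.7)


class TestDirectCall:
    def test_hard_calls_follow_the_likelihood(self):
        pu = _pileup([[10, 0, 5]], [[0, 10, 5]])
        gl = pileup_likelihoods(pu, eps=0.01)
        dm = direct_call(gl, min_depth=2, depth=pu.depth)
        assert list(dm.hard_call[0]) == [0, 2, 1]

    def test_below_min_depth_is_missing(self):
        pu = _pileup([[1]], [[0]])
        gl = pileup_likelihoods(pu, eps=0.01)
        dm = direct_call(gl, min_depth=2, depth=pu.depth)
        assert dm.hard_call[0, 0] == -1 and np.isnan(dm.dosage[0, 0])


class TestEffectiveCoverage:
    @pytest.mark.parametrize(
        "depths,expected",
        [([1, 1, 1, 1, 1], 1.0), ([1, 0, 1, 1, 1], 0.8), ([0, 0, 0, 0, 0], 0.0)],
    )
    def test_fraction_of_covered_panel_sites(self, depths, expected):
        ref = np.array([depths])
        pu = _pileup(ref, np.zeros_like(ref))
        panel = _panel(np.zeros((4, 5)))
        assert effective_coverage(pu, panel)[0] == expected

    def test_empty_panel_rejected(self):
        pu = _pileup([[1]], [[0]])
        panel = _panel(np.zeros((4, 1)))
        panel.site_positions = np.array([], dtype=np.int64)
        with pytest.raises(ValueError):
            effective_coverage(pu, panel)


class TestImpute:
    @pytest.mark.parametrize("switch,copy_err", [(0.1, 0.05), (0.01, 0.01), (0.3, 0.2)])
    def test_forward_backward_matches_exhaustive_enumeration(self, switch, copy_err, rng):
        H = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 1], [1, 1, 0]])
        panel = _panel(H)
        L = rng.random((1, 3, 3)) + 0.05
        gl = GenotypeLikelihoods(["s0"], panel.site_positions, L, np.ones((1, 3), bool))
        params = ImputationParams(switch_rate=switch, copy_error=copy_err)
        fast = impute(gl, panel, params).dosage[0]
        slow = impute_brute_force(gl, panel, params)
        assert np.abs(fast - slow).max() < 1e-10

    def test_deep_reads_matching_a_pair_recover_it_everywhere(self):
        # reads cover only half the sites, exactly matching haplotypes (0, 1);
        # a near-zero switch rate forces the pair through uncovered sites too
        rng = np.random.default_rng(4)
        H = rng.integers(0, 2, (6, 40)).astype(np.int8)
        panel = _panel(H)
        dos_true = H[0] + H[1]
        depth = np.zeros(40, dtype=int)
        depth[::2] = 50
        alt = (depth * dos_true / 2).astype(int)
        pu = _pileup((depth - alt)[None, :], alt[None, :])
        gl = pileup_likelihoods(pu, eps=0.01)
        res = impute(gl, panel, ImputationParams(switch_rate=1e-6, copy_error=1e-3))
        np.testing.assert_allclose(res.dosage[0], dos_true, atol=0.05)

    def test_no_reads_gives_twice_panel_frequency(self):
        rng = np.random.default_rng(5)
        H = rng.integers(0, 2, (30, 12)).astype(np.int8)
        panel = _panel(H)
        pu = _pileup(np.zeros((1, 12), int), np.zeros((1, 12), int))
        gl = pileup_likelihoods(pu, eps=0.01)
        res = impute(gl, panel, ImputationParams(switch_rate=0.05, copy_error=1e-4))
        np.testing.assert_allclose(res.dosage[0], 2 * panel.allele_freq, atol=0.01)

    def test_misaligned_sites_rejected(self):
        H = np.zeros((4, 5), dtype=np.int8)
        panel = _panel(H)
        gl = GenotypeLikelihoods(
            ["s0"], panel.site_positions[:-1], np.ones((1, 4, 3)), np.ones((1, 4), bool)
        )
        with pytest.raises(ValueError):
            impute(gl, panel, ImputationParams())

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_posterior_dosage_always_in_range(self, seed):
        rng = np.random.default_rng(seed)
        H = rng.integers(0, 2, (6, 8)).astype(np.int8)
        depth = rng.poisson(1.0, (2, 8))
        alt = rng.binomial(depth, 0.5)
        pu = _pileup(depth - alt, alt)
        gl = pileup_likelihoods(pu, eps=0.02)
        res = impute(gl, _panel(H), ImputationParams(switch_rate=0.05, copy_error=0.02))
        assert np.all(res.dosage >= 0) and np.all(res.dosage <= 2)


class TestCombiner:
    def _matrices(self, rng, n=20, m=80):
        """Direct calls degrade at low depth, imputed calls err uniformly."""
        truth = rng.integers(0, 3, (n, m)).astype(float)
        depth = 1 + rng.poisson(2.5, (n, m))
        direct = truth.copy()
        flip_direct = rng.random((n, m)) < 0.5 * 0.55**depth
        direct[flip_direct] = (direct[flip_direct] + rng.integers(1, 3, flip_direct.sum())) % 3
        imputed = truth.copy()
        flip_imp = rng.random((n, m)) < 0.12
        imputed[flip_imp] = (imputed[flip_imp] + rng.integers(1, 3, flip_imp.sum())) % 3
        imputed = np.clip(imputed + rng.normal(0, 0.1, (n, m)), 0, 2)
        ids = [f"s{i}" for i in range(n)]
        pos = np.arange(m)
        return (
            DosageMatrix(ids, pos, direct),
            DosageMatrix(ids, pos, imputed),
            DosageMatrix(ids, pos, truth),
            depth,
        )

    def test_agreement_everywhere_leaves_calls_unchanged(self, rng):
        n, m = 12, 30
        truth = rng.integers(0, 3, (n, m)).astype(float)
        ids = [f"s{i}" for i in range(n)]
        dm = lambda: DosageMatrix(ids, np.arange(m), truth.copy())
        model = train_combiner(dm(), dm(), dm(), np.full((n, m), 10), seed=0)
        combined = model.combine(dm(), dm(), np.full((n, m), 10))
        np.testing.assert_allclose(combined.dosage, truth)

    def test_heldout_mse_not_worse_than_either_input(self, rng):
        direct, imputed, truth, depth = self._matrices(rng)
        model = train_combiner(direct, imputed, truth, depth, seed=1)
        combined = model.combine(direct, imputed, depth)
        mse = np.mean((combined.dosage - truth.dosage) ** 2)
        mse_direct = np.mean((direct.dosage - truth.dosage) ** 2)
        mse_imp = np.mean((imputed.dosage - truth.dosage) ** 2)
        assert mse <= min(mse_direct, mse_imp) + 0.01

    def test_zero_depth_always_defers_to_imputation(self, rng):
        direct, imputed, truth, depth = self._matrices(rng)
        model = train_combiner(direct, imputed, truth, depth, seed=2)
        depth0 = np.zeros_like(depth)
        combined = model.combine(direct, imputed, depth0)
        np.testing.assert_allclose(combined.dosage, imputed.dosage)


class TestConcordance:
    def _dm(self, rows):
        arr = np.atleast_2d(np.asarray(rows, dtype=float))
        return DosageMatrix([f"s{i}" for i in range(arr.shape[0])], np.arange(arr.shape[1]), arr)

    def test_identity_gives_perfect_scores(self):
        d = self._dm([[0, 1, 2, 1, 0]])
        out = genotype_concordance(d, self._dm([[0, 1, 2, 1, 0]]))
        assert out.loc[0, "spearman"] == 1.0 and out.loc[0, "mse"] == 0.0

    def test_complement_gives_negative_correlation(self):
        t = np.array([[0, 1, 2, 1, 0, 2]])
        out = genotype_concordance(self._dm(2 - t), self._dm(t))
        assert out.loc[0, "spearman"] == -1.0

    def test_single_flip_mse_hand_value(self):
        t = [[0, 1, 2, 1, 0]]
        c = [[2, 1, 2, 1, 0]]
        out = genotype_concordance(self._dm(c), self._dm(t))
        assert out.loc[0, "mse"] == pytest.approx(0.8)

    def test_constant_call_vector_reports_nan_not_zero(self):
        out = genotype_concordance(self._dm([[1, 1, 1, 1]]), self._dm([[0, 1, 2, 1]]))
        assert np.isnan(out.loc[0, "spearman"])
        assert out.loc[0, "mse"] > 0
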