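"""Unit tests for the population simulator."""

import numpy as np
import pytest

from seqselect import simdata
from seqselect.containers import Pedigree


def adjacent_abs_r(haps_2d):
    """Mean |r| between adjacent variant columns over haplotype rows."""
    H = haps_2d.astype(float)
    H = H[:, H.std(axis=0) > 0]
    C = np.corrcoef(H.T)
    return float(np.nanmean(np.abs(np.diag(C, k=1))))


class TestFounderHaplotypes:
    def test_ld_zero_gives_no_adjacent_correlation(self, small_catalog):
        gm = simdata.simulate_founder_haplotypes(300, small_catalog, 0.0, seed=1)
        H = gm.haplotypes.reshape(-1, small_catalog.n)
        assert adjacent_abs_r(H) < 0.12

    def test_ld_one_copies_pool_haplotypes_exactly(self, small_catalog):
        gm = simdata.simulate_founder_haplotypes(
            50, small_catalog, 1.0, seed=2, pool_size=2
        )
        for c in (1, 2):
            cols = small_catalog.chrom == c
            H = gm.haplotypes.reshape(-1, small_catalog.n)[:, cols]
            assert len(np.unique(H, axis=0)) <= 2

    def test_adjacent_ld_monotone_in_ld_param(self, small_catalog):
        vals = []
        for ld in (0.0, 0.9, 0.999):
            gm = simdata.simulate_founder_haplotypes(200, small_catalog, ld, seed=3)
            vals.append(adjacent_abs_r(gm.haplotypes.reshape(-1, small_catalog.n)))
        assert vals[0] < vals[1] < vals[2]

    def test_marginal_frequencies_match_catalog(self, small_catalog):
        # a large ancestral pool makes the realised frequencies tight;
        # the default small pool is unbiased but noisy per variant
        gm = simdata.simulate_founder_haplotypes(
            400, small_catalog, 0.0, seed=4, pool_size=64
        )
        emp = gm.allele_frequencies()
        assert np.abs(emp - small_catalog.freq).mean() < 0.05
        gm4 = simdata.simulate_founder_haplotypes(400, small_catalog, 0.0, seed=4)
        assert abs((gm4.allele_frequencies() - small_catalog.freq).mean()) < 0.02

    def test_neighbourhood_max_ld_is_high_at_calibrated_param(self, small_catalog):
        # scaled analogue of the 0.9998 calibration: max |r| with nearby
        # variants should be near 1 for almost every variant
        gm = simdata.simulate_founder_haplotypes(200, small_catalog, 0.9998, seed=5)
        cols = small_catalog.chrom == 1
        H = gm.haplotypes.reshape(-1, small_catalog.n)[:, cols].astype(float)
        keep = H.std(axis=0) > 0
        H = H[:, keep]
        C = np.abs(np.corrcoef(H.T))
        np.fill_diagonal(C, 0.0)
        w = 50
        best = [
            C[j, max(0, j - w) : j + w + 1].max() for j in range(C.shape[0])
        ]
        assert np.mean(best) >= 0.9

    def test_input_validation(self, small_catalog):
        with pytest.raises(ValueError):
            simdata.simulate_founder_haplotypes(0, small_catalog, 0.5, seed=1)
        with pytest.raises(ValueError):
            simdata.simulate_founder_haplotypes(2, small_catalog, 1.5, seed=1)


class TestGeneDrop:
    def test_no_offspring_returns_founders(self, small_catalog):
        ped = Pedigree.from_records([("A", "0", "0"), ("B", "0", "0")])
        founders = simdata.simulate_founder_haplotypes(
            2, small_catalog, 0.9, seed=1, founder_ids=ped.ids
        )
        out = simdata.drop_through_pedigree(founders, ped, 1.0, 9, small_catalog)
        assert np.array_equal(out.haplotypes, founders.haplotypes)

    def test_mendelian_consistency_everywhere(self, small_catalog):
        ped = simdata.simulate_pedigree(10, 3, 15, n_sires=3, seed=2)
        founders = simdata.simulate_founder_haplotypes(
            int(ped.is_founder.sum()), small_catalog, 0.9, seed=2,
            founder_ids=ped.ids[ped.is_founder],
        )
        out = simdata.drop_through_pedigree(founders, ped, 1.0, 3, small_catalog)
        for i in range(ped.n):
            for g, parent in enumerate((ped.sire[i], ped.dam[i])):
                if parent == -1:
                    continue
                child = out.haplotypes[i, g]
                p0, p1 = out.haplotypes[parent]
                assert np.all((child == p0) | (child == p1))

    def test_crossover_count_is_poisson_with_given_mean(self):
        # one chromosome of 1 Morgan: Monte Carlo mean crossover count ~ 1
        cat = simdata.build_catalog(1, 50, 1_000_000, seed=11)
        rng = np.random.default_rng(0)
        parent = rng.integers(0, 2, size=(2, cat.n)).astype(np.int8)
        counts = [
            simdata.simulate_gamete(parent, cat, 1.0, 1_000_000, rng)[1]
            for _ in range(10_000)
        ]
        assert abs(np.mean(counts) - 1.0) < 0.03


class TestArraySubsets:
    def test_even_spacing_and_nesting(self, small_catalog):
        # 400 variants, tiers (80, 40): strides of 5 then 10
        cat = simdata.assign_array_subsets(small_catalog, (80, 40, 8))
        idx1 = np.flatnonzero(cat.in_600k)
        assert np.array_equal(idx1, np.arange(0, 400, 5))
        idx2 = np.flatnonzero(cat.in_60k)
        assert np.array_equal(idx2, np.arange(0, 400, 10))
        assert set(np.flatnonzero(cat.in_12k)) <= set(idx2) <= set(idx1)
        cat.validate()  # nesting invariant

    def test_full_size_tier_flags_everything(self, small_catalog):
        cat = simdata.assign_array_subsets(small_catalog, (small_catalog.n,))
        assert cat.in_600k.all()

    def test_per_chromosome_proportionality(self, small_catalog):
        cat = simdata.assign_array_subsets(small_catalog, (40,))
        for c in (1, 2):
            n_c = int((cat.in_600k & (cat.chrom == c)).sum())
            assert abs(n_c - 20) <= 1

    def test_tier_order_enforced(self, small_catalog):
        with pytest.raises(ValueError):
            simdata.assign_array_subsets(small_catalog, (10, 20))
        with pytest.raises(ValueError):
            simdata.assign_array_subsets(small_catalog, (small_catalog.n + 1,))


class TestQTLEffects:
    @pytest.mark.parametrize(
        "q,alpha", [(2.0, 2.0), (0.0, 0.0), (-3.0, -8.1), (1.0, 1.0 / 2.7)]
    )
    def test_heavy_tail_transform(self, q, alpha):
        assert simdata.heavy_tail_effect(q, 2.7) == pytest.approx(alpha)

    def test_architecture_consistency(self, small_catalog):
        arch = simdata.simulate_qtl_effects(50, small_catalog, seed=3, n_traits=4)
        assert arch.q.shape == (4, 50)
        p = small_catalog.freq[arch.indices]
        expected_v = 2 * p * (1 - p) * arch.alpha**2
        np.testing.assert_allclose(arch.v, expected_v)
        assert len(np.unique(arch.indices)) == 50

    def test_rejects_bad_inputs(self, small_catalog):
        with pytest.raises(ValueError):
            simdata.simulate_qtl_effects(0, small_catalog)
        with pytest.raises(ValueError):
            simdata.simulate_qtl_effects(small_catalog.n + 1, small_catalog)


class TestVarianceConcentration:
    def test_toy_shares(self, small_catalog):
        arch = simdata.simulate_qtl_effects(4, small_catalog, seed=1)
        arch.v[:] = [[4.0, 3.0, 2.0, 1.0]]
        assert simdata.variance_concentration(arch, 1) == pytest.approx(40.0)
        assert simdata.variance_concentration(arch, 4) == pytest.approx(100.0)

    def test_all_zero_errors(self, small_catalog):
        arch = simdata.simulate_qtl_effects(4, small_catalog, seed=1)
        arch.v[:] = 0.0
        with pytest.raises(ValueError):
            simdata.variance_concentration(arch, 1)


class TestTBVAndPhenotypes:
    def test_tbv_is_dosage_dot_alpha(self, small_catalog, make_gm):
        arch = simdata.simulate_qtl_effects(3, small_catalog, seed=1, n_traits=2)
        D = np.zeros((3, small_catalog.n), dtype=np.int8)
        D[:, arch.indices] = [[0, 1, 2], [2, 2, 2], [1, 0, 0]]
        gm = make_gm(D, variant_ids=small_catalog.ids)
        tbv = simdata.compute_tbv(gm, arch)
        oracle = D[:, arch.indices].astype(float) @ arch.alpha.T
        np.testing.assert_allclose(tbv, oracle)

    def test_single_qtl_unit_effect(self, small_catalog, make_gm):
        arch = simdata.simulate_qtl_effects(1, small_catalog, seed=2)
        arch.alpha[:] = 1.0
        D = np.zeros((3, small_catalog.n), dtype=np.int8)
        D[:, arch.indices[0]] = [0, 1, 2]
        tbv = simdata.compute_tbv(make_gm(D), arch)
        np.testing.assert_allclose(tbv.ravel(), [0, 1, 2])

    def test_reliability_one_reproduces_tbv(self, rng):
        tbv = rng.standard_normal(50)
        phen = simdata.simulate_phenotypes(tbv, 1.0, seed=1)
        np.testing.assert_allclose(phen.y.ravel(), tbv)

    def test_reliability_half_gives_half_squared_correlation(self, rng):
        tbv = rng.standard_normal(10_000)
        phen = simdata.simulate_phenotypes(tbv, 0.5, seed=2)
        r2 = np.corrcoef(phen.y.ravel(), tbv)[0, 1] ** 2
        assert r2 == pytest.approx(0.5, abs=0.02)

    def test_constant_tbv_warns_and_copies(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            phen = simdata.simulate_phenotypes(np.ones(10), 0.5, seed=3)
        assert np.all(phen.y == 1.0)
        assert any("zero TBV variance" in r.message for r in caplog.records)

    def test_bad_reliability_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_phenotypes(np.arange(5.0), 0.0, seed=1)


class TestPedigreeContainer:
    def test_orders_and_cycles_rejected(self):
        with pytest.raises(ValueError):
            Pedigree(np.array(["a", "b"]), np.array([1, -1]), np.array([-1, -1]))
        with pytest.raises(ValueError):
            Pedigree.from_records([("a", "a", "0")])

    def test_simulated_pedigree_is_valid(self):
        ped = simdata.simulate_pedigree(20, 4, 30, n_sires=5, seed=1)
        assert ped.n == 20 + 4 * 30
        assert int(ped.is_founder.sum()) == 20

    def test_a_matrix_full_sibs(self):
        ped = Pedigree.from_records(
            [("s", "0", "0"), ("d", "0", "0"), ("x", "s", "d"), ("y", "s", "d")]
        )
        A = ped.a_matrix()
        assert A[2, 3] == pytest.approx(0.5)
        assert A[2, 2] == pytest.approx(1.0)
        assert A[0, 2] == pytest.approx(0.5)

    def test_a_inverse_inverts_a(self):
        # one generation from unrelated founders: no inbreeding, so the
        # Henderson rules (which ignore inbreeding) are exact
        ped = simdata.simulate_pedigree(6, 1, 10, n_sires=2, seed=3)
        A = ped.a_matrix()
        Ainv = ped.a_inverse().toarray()
        np.testing.assert_allclose(A @ Ainv, np.eye(ped.n), atol=1e-8)


class TestHeavyTailProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.floats(-5, 5, allow_subnormal=False), st.floats(1.05, 4.0))
    def test_effect_sign_and_growth(self, q, base):
        """alpha keeps the sign of q and |alpha| grows with |q|."""
        a = float(simdata.heavy_tail_effect(q, base))
        assert np.sign(a) == np.sign(q)
        bigger = float(simdata.heavy_tail_effect(abs(q) + 0.5, base))
        assert bigger >= abs(a)
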