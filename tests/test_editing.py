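"""Unit tests for the edit rules, each against its worked boundary case."""

import numpy as np
import pytest

from seqselect import editing
from seqselect.containers import MISSING, VariantCatalog
from seqselect.editing import EditConfig


def catalog_with_freqs(freqs, protected=None):
    m = len(freqs)
    return VariantCatalog(
        chrom=np.ones(m, dtype=int),
        pos=np.arange(1, m + 1) * 100,
        ref=np.repeat("A", m),
        alt=np.repeat("C", m),
        freq=np.asarray(freqs, dtype=float),
        protected=protected,
    )


class TestMafFilter:
    def test_boundary_cases(self):
        cat = catalog_with_freqs([0.005, 0.02, 0.99, 0.995])
        keep = editing.maf_filter(cat, 0.01)
        # 0.005 removed; 0.02 kept; p=0.99 has MAF exactly 0.01, kept
        assert list(keep) == [False, True, True, False]

    def test_protected_always_kept(self):
        cat = catalog_with_freqs([0.001, 0.002], protected=[True, False])
        assert list(editing.maf_filter(cat, 0.01)) == [True, False]

    def test_all_below_threshold_empty(self):
        cat = catalog_with_freqs([0.001, 0.002])
        assert not editing.maf_filter(cat, 0.01).any()

    def test_idempotent(self):
        cat = catalog_with_freqs([0.005, 0.2, 0.4])
        keep = editing.maf_filter(cat, 0.01)
        again = editing.maf_filter(cat.subset(keep), 0.01)
        assert again.all()


class TestGprobFilter:
    def test_masks_low_confidence_calls(self, make_gm):
        gp = np.array([[[0.97, 0.02, 0.01], [0.99, 0.01, 0.0]]])
        gm = make_gm([[0, 0]], call_probs=gp)
        out = editing.gprob_filter(gm, 0.98)
        assert out.dosages[0, 0] == MISSING
        assert out.dosages[0, 1] == 0

    def test_threshold_zero_masks_nothing(self, make_gm):
        gp = np.full((2, 3, 3), 1 / 3.0)
        gm = make_gm(np.ones((2, 3)), call_probs=gp)
        assert not editing.gprob_filter(gm, 0.0).missing_mask.any()

    def test_requires_probabilities(self, make_gm):
        with pytest.raises(ValueError):
            editing.gprob_filter(make_gm([[0, 1]]), 0.98)


class TestMissingnessFilter:
    @staticmethod
    def _column(p, miss_frac, n=100):
        """Column with exactly miss_frac missing and alt frequency ~ p."""
        n_miss = int(round(miss_frac * n))
        n_called = n - n_miss
        n_alt = int(round(2 * n_called * p))
        calls = np.concatenate(
            [np.full(n_alt // 2, 2), np.full(n_alt % 2, 1),
             np.zeros(n_called - n_alt // 2 - n_alt % 2)]
        ).astype(np.int8)
        return np.concatenate([calls, np.full(n_miss, MISSING)]).astype(np.int8)

    @pytest.mark.parametrize(
        "p,miss_frac,kept",
        [
            (0.50, 0.26, False),  # limit MAF/2 = 0.25
            (0.05, 0.06, False),  # low-MAF limit 5%
            (0.20, 0.09, True),   # limit ~0.10
            (0.50, 0.25, True),   # boundary not "more than"
        ],
    )
    def test_rules(self, make_gm, p, miss_frac, kept):
        gm = make_gm(self._column(p, miss_frac)[:, None])
        assert editing.missingness_filter(gm, EditConfig())[0] == kept


class TestHWEFilter:
    def _gm_with_het_fraction(self, make_gm, p, het_frac, n=200):
        # exact construction: n chosen so counts are integral and the
        # realised frequency equals p exactly
        n_het = int(round(het_frac * n))
        n_alt_hom = int(round((p * 2 * n - n_het) / 2))
        col = np.array(
            [1] * n_het + [2] * n_alt_hom + [0] * (n - n_het - n_alt_hom),
            dtype=np.int8,
        )
        gm = make_gm(col[:, None])
        assert gm.allele_frequencies()[0] == p
        return gm

    def test_excess_heterozygotes_removed(self, make_gm):
        gm = self._gm_with_het_fraction(make_gm, 0.5, 0.76)
        assert not editing.hwe_excess_het_filter(gm, 1.5)[0]

    def test_boundary_kept(self, make_gm):
        gm = self._gm_with_het_fraction(make_gm, 0.5, 0.75)
        assert editing.hwe_excess_het_filter(gm, 1.5)[0]

    def test_moderate_het_low_maf_kept(self, make_gm):
        gm = self._gm_with_het_fraction(make_gm, 0.1, 0.20)
        # limit 1.5 * 2*0.1*0.9 = 0.27
        assert editing.hwe_excess_het_filter(gm, 1.5)[0]


class TestGenicRetain:
    def test_boundary_distance_inclusive(self):
        cat = VariantCatalog(
            chrom=[1, 1], pos=[12_500, 12_501], ref=["A", "A"], alt=["C", "C"],
            freq=[0.5, 0.5],
        )
        prot = editing.genic_retain(cat, [(1, 10_000, 10_000)], 2500)
        assert list(prot) == [True, False]

    def test_matches_brute_force_scan(self, small_catalog, rng):
        regions = [
            (int(c), int(p), int(p) + 50)
            for c, p in zip(
                rng.choice(small_catalog.chrom, 20), rng.choice(small_catalog.pos, 20)
            )
        ]
        prot = editing.genic_retain(small_catalog, regions, 300)
        for j in range(small_catalog.n):
            d = min(
                (
                    max(s - small_catalog.pos[j], small_catalog.pos[j] - e, 0)
                    for c, s, e in regions
                    if c == small_catalog.chrom[j]
                ),
                default=np.inf,
            )
            assert prot[j] == (d <= 300)

    def test_malformed_interval(self, small_catalog):
        with pytest.raises(ValueError):
            editing.genic_retain(small_catalog, [(1, 100, 50)], 10)


def brute_force_ld_prune(D, chrom, protected, window, rmax):
    """Independent re-trace of the scan rule using numpy correlations."""
    m = D.shape[1]

    def r_of(i, j):
        x, y = D[:, i].astype(float), D[:, j].astype(float)
        ok = (x >= 0) & (y >= 0)
        if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
            return 0.0
        return np.corrcoef(x[ok], y[ok])[0, 1]

    kept = []
    for i in range(m):
        removed = False
        if not protected[i]:
            same = [j for j in kept if chrom[j] == chrom[i]][-window:]
            for j in reversed(same):
                if abs(r_of(i, j)) > rmax:
                    removed = True
                    break
            if not removed:
                # protected variants ahead within the raw window also evict
                for j in range(i + 1, min(i + window + 1, m)):
                    if chrom[j] != chrom[i]:
                        break
                    if protected[j] and abs(r_of(i, j)) > rmax:
                        removed = True
                        break
        if not removed:
            kept.append(i)
    keep = np.zeros(m, dtype=bool)
    keep[kept] = True
    return keep


class TestLDPrune:
    def _correlated_triple(self, make_gm, rng):
        x = rng.binomial(2, 0.5, 200).astype(np.int8)
        noise = rng.binomial(2, 0.5, 200).astype(np.int8)
        D = np.stack([x, x, noise], axis=1)  # r(1,2)=1, r(1,3)~0
        return make_gm(D)

    def test_drops_duplicate_keeps_independent(self, make_gm, rng):
        gm = self._correlated_triple(make_gm, rng)
        keep = editing.ld_prune(gm, window=10, rmax=0.95)
        assert list(keep) == [True, False, True]

    def test_no_high_ld_keeps_all(self, make_gm, rng):
        D = rng.binomial(2, 0.5, size=(300, 5)).astype(np.int8)
        assert editing.ld_prune(make_gm(D), window=4, rmax=0.99).all()

    def test_protected_wins_over_earlier_duplicate(self, make_gm, rng):
        gm = self._correlated_triple(make_gm, rng)
        keep = editing.ld_prune(
            gm, window=10, rmax=0.95, protected=np.array([False, True, False])
        )
        assert list(keep) == [False, True, True]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_panels(self, make_gm, seed):
        rng = np.random.default_rng(seed)
        n, m = 60, 120
        base = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(np.int8)
        # plant blocks of near-duplicates
        for j in range(0, m - 3, 7):
            base[:, j + 1] = base[:, j]
            base[:, j + 2] = 2 - base[:, j]
        base[rng.random((n, m)) < 0.02] = MISSING
        chrom = np.repeat([1, 2], m // 2)
        protected = rng.random(m) < 0.1
        keep = editing.ld_prune(
            make_gm(base), window=5, rmax=0.9, protected=protected, chrom=chrom
        )
        oracle = brute_force_ld_prune(base, chrom, protected, 5, 0.9)
        assert np.array_equal(keep, oracle)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_kept_set_is_conflict_free(self, make_gm, seed):
        rng = np.random.default_rng(seed)
        n, m = 50, 500
        D = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(np.int8)
        for j in range(0, m - 1, 3):
            if rng.random() < 0.5:
                D[:, j + 1] = D[:, j]
        keep = editing.ld_prune(make_gm(D), window=10, rmax=0.9)
        kept = np.flatnonzero(keep)
        for a_pos, i in enumerate(kept):
            for j in kept[max(0, a_pos - 10) : a_pos]:
                r = np.corrcoef(D[:, i].astype(float), D[:, j].astype(float))[0, 1]
                assert abs(r) <= 0.9 + 1e-12

    def test_idempotent(self, make_gm, rng):
        D = rng.binomial(2, 0.5, size=(100, 30)).astype(np.int8)
        D[:, 1] = D[:, 0]
        keep = editing.ld_prune(make_gm(D), window=5, rmax=0.9)
        sub = make_gm(D[:, keep])
        assert editing.ld_prune(sub, window=5, rmax=0.9).all()

    def test_window_must_be_positive(self, make_gm, rng):
        D = rng.binomial(2, 0.5, size=(10, 3)).astype(np.int8)
        with pytest.raises(ValueError):
            editing.ld_prune(make_gm(D), window=0)

    def test_sklearn_wrapper_round_trip(self, rng):
        D = rng.binomial(2, 0.5, size=(80, 20)).astype(np.int8)
        D[:, 5] = D[:, 4]
        pruner = editing.LDPruner(window=5, rmax=0.9).fit(D)
        out = pruner.transform(D)
        assert out.shape[1] == int(pruner.keep_mask_.sum())
        assert pruner.get_params()["window"] == 5


class TestOrientation:
    def _pair(self, make_gm, rng, flip=False, scramble=False):
        x = rng.binomial(2, 0.5, 50).astype(np.int8)
        y = x.copy()
        if flip:
            y = (2 - y).astype(np.int8)
        if scramble:
            y = rng.permutation(y)
        chip = make_gm(x[:, None], variant_ids=["v"])
        seq = make_gm(y[:, None], variant_ids=["v"])
        return chip, seq

    def test_keep_flip_drop(self, make_gm, rng):
        for flip, scramble, expected in [
            (False, False, "keep"), (True, False, "flip"), (False, True, "drop"),
        ]:
            chip, seq = self._pair(make_gm, rng, flip, scramble)
            actions = editing.reconcile_orientation(
                chip, seq, chip.animal_ids, rmin=0.95
            )
            assert actions["action"].iloc[0] == expected

    def test_flip_is_involution_and_fixes_sign(self, make_gm, rng):
        chip, seq = self._pair(make_gm, rng, flip=True)
        actions = editing.reconcile_orientation(chip, seq, chip.animal_ids)
        once = editing.apply_orientation(chip, actions)
        r = np.corrcoef(once.dosages[:, 0].astype(float),
                        seq.dosages[:, 0].astype(float))[0, 1]
        assert r == pytest.approx(1.0)
        twice = editing.apply_orientation(once, actions)
        assert np.array_equal(twice.dosages, chip.dosages)

    def test_zero_variance_dropped(self, make_gm, rng):
        chip = make_gm(np.zeros((10, 1), dtype=np.int8), variant_ids=["v"])
        seq = make_gm(rng.binomial(2, 0.5, 10).astype(np.int8)[:, None],
                      variant_ids=["v"])
        actions = editing.reconcile_orientation(chip, seq, chip.animal_ids)
        assert actions["action"].iloc[0] == "drop"

    def test_merge_prefers_sequence_calls(self, make_gm, rng):
        chip, seq = self._pair(make_gm, rng, flip=False)
        seq.dosages[0, 0] = 2
        chip.dosages[0, 0] = 0
        actions = editing.reconcile_orientation(chip, seq, chip.animal_ids[1:])
        merged = editing.merge_chip_and_sequence(chip, seq, actions)
        row = list(merged.animal_ids).index(seq.animal_ids[0])
        assert merged.dosages[row, 0] == 2


class TestMendelianConflicts:
    def test_opposite_homozygotes_blanked(self, make_gm, trio_pedigree):
        # animals: S, D, O1(S,D), O2(S,-); 10 variants each -> 40 cells
        D = np.ones((4, 10), dtype=np.int8)
        D[0, 0] = 2  # sire hom-alt
        D[2, 0] = 0  # O1 hom-ref -> conflict
        D[0, 1] = 2
        D[3, 1] = 0  # O2 conflict with sire
        D[1, 2] = 2
        D[2, 2] = 1  # het: no conflict
        gm = make_gm(D, animal_ids=trio_pedigree.ids)
        out, rate = editing.set_mendelian_conflicts_missing(gm, trio_pedigree)
        assert out.dosages[2, 0] == MISSING
        assert out.dosages[3, 1] == MISSING
        assert out.dosages[0, 0] == 2  # parent untouched by default
        assert out.dosages[2, 2] == 1
        assert rate == pytest.approx(2 / 40)

    def test_both_sides_mode(self, make_gm, trio_pedigree):
        D = np.ones((4, 5), dtype=np.int8)
        D[0, 0], D[2, 0] = 2, 0
        gm = make_gm(D, animal_ids=trio_pedigree.ids)
        out, rate = editing.set_mendelian_conflicts_missing(
            gm, trio_pedigree, both_sides=True
        )
        assert out.dosages[0, 0] == MISSING and out.dosages[2, 0] == MISSING
        assert rate == pytest.approx(2 / 20)


class TestEditComposition:
    def test_report_stages_are_consistent(self, make_gm, small_catalog, rng):
        D = rng.binomial(2, small_catalog.freq, size=(80, small_catalog.n)).astype(np.int8)
        D[:, 10] = D[:, 11]
        keep, report = editing.apply_variant_edits(
            make_gm(D, variant_ids=small_catalog.ids), small_catalog,
            EditConfig(ld_window=10),
        )
        assert list(report["stage"].str.startswith(("maf", "ld"))) == [True, True]
        assert report["variants_in"].iloc[0] == small_catalog.n
        assert report["kept"].iloc[0] == report["variants_in"].iloc[1]
        assert report["kept"].iloc[1] == int(keep.sum())
        assert (report["variants_in"] - report["removed"] == report["kept"]).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EditConfig(maf_min=1.5)
        with pytest.raises(ValueError):
            EditConfig(het_excess_factor=0.5)


class TestFilterIdempotence:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_variant_filters_are_idempotent(self, seed):
        """Applying a frequency-level filter to its own output removes
        nothing more."""
        from seqselect.containers import GenotypeMatrix

        rng = np.random.default_rng(seed)
        D = rng.choice(
            np.array([0, 1, 2, MISSING], dtype=np.int8),
            size=(40, 12), p=[0.3, 0.3, 0.3, 0.1],
        )
        gm = GenotypeMatrix(np.arange(40), np.arange(12), D)
        cfg = EditConfig()
        sub = gm.subset_variants(editing.missingness_filter(gm, cfg))
        assert editing.missingness_filter(sub, cfg).all()
        sub2 = gm.subset_variants(editing.hwe_excess_het_filter(gm))
        assert editing.hwe_excess_het_filter(sub2).all()
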