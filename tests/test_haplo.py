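"""EM haplotype estimation, LD statistics, Gabriel blocks, frequency tests."""

import numpy as np
import pytest

from acylpop import catalog, haplo, synthdata
from acylpop.model import Cohort, VariantRecord

from conftest import make_variants, tiny_cohort


def cpt2_loci():
    return [v for v in catalog.all_variants()
            if v.name in catalog.CPT2_HAPLOTYPE_LOCI]


class TestEm:
    def test_no_phase_ambiguity_recovers_proportions(self):
        # all individuals doubly homozygous: frequencies are the observed
        # haplotype proportions, immediately
        g = np.array([[2, 2]] * 30 + [[0, 0]] * 70, dtype=np.int8)
        table = haplo.em_haplotype_frequencies(g)
        assert table.frequencies["11"] == pytest.approx(0.3, abs=1e-12)
        assert table.frequencies["00"] == pytest.approx(0.7, abs=1e-12)
        assert table.iterations <= 2
        assert table.converged

    def test_matches_grid_search_oracle(self):
        # 20 AABB + 20 aabb + 10 AaBb: compare EM to a 1e-5 grid over the
        # only free parameter (the coupling-haplotype frequency)
        g = np.array([[2, 2]] * 20 + [[0, 0]] * 20 + [[1, 1]] * 10,
                     dtype=np.int8)
        table = haplo.em_haplotype_frequencies(g, tol=1e-12)
        p_a = p_b = 0.5  # allele frequencies are fixed by genotype counts

        def loglik(f_ab):
            f_ab_ = f_ab
            f_a_b = p_a - f_ab_          # A-b haplotype
            f_ab2 = p_b - f_ab_          # a-B haplotype
            f_rest = 1 - p_a - p_b + f_ab_
            p22 = f_ab_**2
            p00 = f_rest**2
            p11 = 2 * f_ab_ * f_rest + 2 * f_a_b * f_ab2
            with np.errstate(divide="ignore"):
                return (20 * np.log(p22) + 20 * np.log(p00)
                        + 10 * np.log(p11))

        grid = np.arange(0.0, 0.5 + 1e-9, 1e-5)
        best = grid[np.argmax([loglik(f) for f in grid])]
        assert table.frequencies["11"] == pytest.approx(best, abs=1e-4)

    def test_loglikelihood_monotone(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, (60, 4)).astype(np.int8)
        table = haplo.em_haplotype_frequencies(g)
        diffs = np.diff(table.loglik_trace)
        assert (diffs >= -1e-9).all()

    def test_frequencies_form_distribution(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, (40, 3)).astype(np.int8)
        table = haplo.em_haplotype_frequencies(g)
        vals = np.array(list(table.frequencies.values()))
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(1.0, abs=1e-8)

    def test_published_cpt2_haplotypes_recovered(self):
        spec = synthdata.HaplotypeSpec(
            cpt2_loci(), catalog.CPT2_HAPLOTYPES, 100, seed=12)
        cohort = synthdata.simulate_haplotype_cohort(spec)
        table = haplo.cohort_haplotypes(cohort, [v.key for v in cpt2_loci()])
        se = 3 * np.sqrt(0.28 * 0.72 / 200)
        assert abs(table.frequency("GAC") - 0.28) < se

    def test_recovery_within_three_se_over_many_seeds(self):
        # unphase -> re-estimate across 100 seeds: every haplotype estimate
        # within 3 standard errors of the realized phased-truth frequency
        # (the multinomial draw itself strays past 3 SE of the *nominal*
        # frequency in ~1% of seeds, so phase-inference error is measured
        # against the truth the generator actually placed)
        loci = cpt2_loci()
        for seed in range(100):
            spec = synthdata.HaplotypeSpec(
                loci, catalog.CPT2_HAPLOTYPES, 100, seed=seed)
            cohort = synthdata.simulate_haplotype_cohort(spec)
            table = haplo.cohort_haplotypes(cohort, [v.key for v in loci])
            realized = np.bincount(cohort.phased_haplotypes.ravel(),
                                   minlength=4) / 200
            for i, h in enumerate(cohort.haplotype_strings):
                f = catalog.CPT2_HAPLOTYPES[h]
                se = np.sqrt(f * (1 - f) / 200)
                assert abs(table.frequency(h) - realized[i]) < 3 * se + 1e-9, (
                    seed, h)

    def test_all_missing_locus_rejected(self):
        g = np.array([[1, -1], [0, -1]], dtype=np.int8)
        with pytest.raises(ValueError):
            haplo.em_haplotype_frequencies(g)

    def test_locus_bound_enforced(self):
        g = np.zeros((4, 13), dtype=np.int8)
        with pytest.raises(ValueError):
            haplo.em_haplotype_frequencies(g)


class TestLdCoefficients:
    def test_independent_loci_zero(self):
        d, dp, r2 = haplo.ld_coefficients(0.25, 0.5, 0.5)
        assert (d, dp, r2) == (0.0, 0.0, 0.0)

    def test_coupling_only_complete_ld(self):
        d, dp, r2 = haplo.ld_coefficients(0.3, 0.3, 0.3)
        assert dp == pytest.approx(1.0)

    def test_hand_computed_fixture(self):
        d, dp, r2 = haplo.ld_coefficients(0.4, 0.5, 0.5)
        assert d == pytest.approx(0.15)
        assert dp == pytest.approx(0.6)
        assert r2 == pytest.approx(0.36)

    def test_monomorphic_undefined(self):
        _, dp, r2 = haplo.ld_coefficients(0.0, 0.0, 0.5)
        assert np.isnan(dp) and np.isnan(r2)

    def test_bounds_over_random_haplotype_draws(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            f = rng.dirichlet([1, 1, 1, 1])  # (ab, Ab, aB, AB)
            f_a, f_b = f[1] + f[3], f[2] + f[3]
            if min(f_a, f_b) < 1e-3 or max(f_a, f_b) > 1 - 1e-3:
                continue
            _, dp, r2 = haplo.ld_coefficients(f[3], f_a, f_b)
            assert -1 - 1e-9 <= dp <= 1 + 1e-9
            assert -1e-9 <= r2 <= 1 + 1e-9
            assert r2 <= abs(dp) + 1e-9


class TestLdStats:
    def test_complete_ld_pair(self):
        loci = make_variants(2)
        spec = synthdata.HaplotypeSpec(loci, {"GG": 0.66, "AA": 0.34},
                                       100, seed=3)
        cohort = synthdata.simulate_haplotype_cohort(spec)
        s = haplo.ld_stats(cohort, 0, 1)
        assert s.dprime == pytest.approx(1.0, abs=1e-6)
        assert s.r2 == pytest.approx(1.0, abs=1e-6)
        assert s.lod > 10

    def test_independent_pair_low_lod(self):
        rng = np.random.default_rng(4)
        g = np.column_stack([rng.binomial(2, 0.5, 300),
                             rng.binomial(2, 0.5, 300)]).astype(np.int8)
        s = haplo.ld_stats(tiny_cohort(g), 0, 1)
        assert abs(s.d) < 0.05
        assert s.lod < 2


class TestGabrielBlocks:
    @staticmethod
    def _trio_plus_distant(seed=3):
        loci = [VariantRecord("chr22", p, "A", "G", "CPT1B", "missense")
                for p in (51009000, 51014000, 51016500, 51100000)]
        spec = synthdata.HaplotypeSpec(
            loci[:3], {"GGG": 0.66, "AAA": 0.34}, 100, seed=seed)
        trio = synthdata.simulate_haplotype_cohort(spec)
        rng = np.random.default_rng(seed + 1)
        g4 = rng.binomial(2, 0.5, 100).astype(np.int8)
        return Cohort(variants=loci, samples=trio.samples,
                      genotypes=np.column_stack([trio.genotypes, g4]))

    def test_complete_ld_pair_forms_block(self):
        cohort = self._trio_plus_distant()
        pair = cohort.subset_variants([0, 1])
        blocks = haplo.ld_blocks(pair)
        assert len(blocks) == 1
        assert blocks[0].n_markers == 2

    def test_equilibrium_markers_form_no_blocks(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.5, (200, 3)).astype(np.int8)
        cohort = tiny_cohort(g)
        assert haplo.ld_blocks(cohort) == []

    def test_linked_trio_with_distant_marker(self):
        # emulates the published 8 kb three-marker block: the trio blocks
        # together, the distant independent marker stays out
        blocks = haplo.ld_blocks(self._trio_plus_distant())
        assert len(blocks) == 1
        blk = blocks[0]
        assert (blk.start_index, blk.end_index) == (0, 2)
        assert blk.span_bp == 7500
        assert blk.strong_fraction == 1.0

    def test_low_maf_markers_excluded_from_pair_counting(self):
        positions = [100, 200]
        lo = np.full((2, 2), np.nan)
        hi = np.full((2, 2), np.nan)
        lo[0, 1], hi[0, 1] = 0.9, 1.0
        blocks = haplo.gabriel_blocks(positions, lo, hi, maf=[0.01, 0.4])
        assert blocks == []

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            haplo.gabriel_blocks([200, 100], np.zeros((2, 2)),
                                 np.zeros((2, 2)), [0.3, 0.3])

    def test_bootstrap_ci_agrees_with_profile_in_complete_ld(self):
        cohort = self._trio_plus_distant()
        lo_p, hi_p = haplo.dprime_ci(cohort, 0, 1, method="profile")
        lo_b, hi_b = haplo.dprime_ci(cohort, 0, 1, method="bootstrap", seed=1)
        assert lo_p > 0.9 and hi_p == pytest.approx(1.0, abs=1e-6)
        assert lo_b > 0.9 and hi_b == pytest.approx(1.0, abs=1e-6)


class TestHaplotypeFreqCompare:
    def test_equal_frequencies_not_significant(self):
        p = haplo.haplotype_freq_compare(100, 200, freq_b=0.5)
        assert p >= 0.5

    def test_two_proportion_matches_statsmodels(self):
        # 132/200 (0.66) vs 76/166 (0.458), one-sided pooled z
        from statsmodels.stats.proportion import proportions_ztest

        p = haplo.haplotype_freq_compare(
            132, 200, count_b=76, chrom_b=166, mode="two_proportion")
        _, p_sm = proportions_ztest([132, 76], [200, 166],
                                    alternative="larger")
        assert p == pytest.approx(p_sm, rel=1e-9)
        # same order as the published binomial-test value 7.5e-5
        assert 1e-5 < p < 3e-4

    def test_one_sample_binomial_published_magnitude(self):
        # 0.66 in 200 Inuit chromosomes against the Asian frequency 0.46
        p = haplo.haplotype_freq_compare(132, 200, freq_b=0.46)
        assert 1e-9 < p < 1e-3

    def test_zero_over_zero_degenerate(self):
        assert haplo.haplotype_freq_compare(0, 200, freq_b=0.0) == 1.0

    def test_zero_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            haplo.haplotype_freq_compare(0, 0, freq_b=0.5)
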