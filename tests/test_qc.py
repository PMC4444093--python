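"""QC filters, allele frequencies, HWE exact test, concordance, IBS/MDS."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from acylpop import qc, synthdata
from acylpop.model import Cohort, VariantRecord

from conftest import make_variants, tiny_cohort


def full_metrics(shape, dp=100.0, gq=99.0, af=0.5):
    return dict(
        depth=np.full(shape, dp),
        gq=np.full(shape, gq),
        alt_fraction=np.full(shape, af),
    )


class TestFilterGenotypes:
    def test_depth_boundary_masks_single_genotype(self):
        g = np.ones((3, 2), dtype=np.int8)
        cohort = tiny_cohort(g, **full_metrics((3, 2)))
        cohort.depth[1, 0] = 19.0
        out, masked = qc.filter_genotypes(cohort)
        assert masked == 1
        assert out.genotypes[1, 0] == -1
        assert (out.genotypes.ravel() != -1).sum() == 5

    def test_passing_cohort_unchanged(self):
        cohort = tiny_cohort(np.ones((4, 3), dtype=np.int8),
                             **full_metrics((4, 3)))
        out, masked = qc.filter_genotypes(cohort)
        assert masked == 0
        assert (out.genotypes == cohort.genotypes).all()

    def test_known_failure_count(self):
        # plant exactly 7 failing genotypes across the three filters
        g = np.ones((5, 4), dtype=np.int8)
        cohort = tiny_cohort(g, **full_metrics((5, 4)))
        for i, j in [(0, 0), (1, 1), (2, 2)]:
            cohort.depth[i, j] = 5.0
        for i, j in [(3, 0), (4, 1)]:
            cohort.gq[i, j] = 2.0
        for i, j in [(0, 3), (1, 3)]:
            cohort.alt_fraction[i, j] = 0.1
        _, masked = qc.filter_genotypes(cohort)
        assert masked == 7

    def test_alt_fraction_ignored_for_hom_ref(self):
        g = np.zeros((2, 2), dtype=np.int8)
        cohort = tiny_cohort(g, **full_metrics((2, 2), af=0.0))
        _, masked = qc.filter_genotypes(cohort)
        assert masked == 0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, (10, 5)).astype(np.int8)
        cohort = tiny_cohort(
            g,
            depth=rng.uniform(0, 60, (10, 5)),
            gq=rng.uniform(0, 40, (10, 5)),
            alt_fraction=rng.uniform(0, 1, (10, 5)),
        )
        once, m1 = qc.filter_genotypes(cohort)
        twice, m2 = qc.filter_genotypes(once)
        assert m2 == 0
        assert (once.genotypes == twice.genotypes).all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            qc.QCThresholds(min_depth=-1)


class TestAlleleFrequency:
    def test_het_hom_mix_reproduces_high_frequency(self):
        g = np.array([[1]] * 9 + [[2]] * 91, dtype=np.int8)
        cohort = tiny_cohort(g)
        freq, derived, called = qc.allele_frequency(cohort, 0)
        assert (freq, derived, called) == (pytest.approx(0.955), 191, 200)

    def test_all_hom_ref_zero(self):
        cohort = tiny_cohort(np.zeros((10, 1), dtype=np.int8))
        assert qc.allele_frequency(cohort, 0)[0] == 0.0

    def test_missing_excluded_from_denominator(self):
        cohort = tiny_cohort(np.array([[1], [2], [-1]], dtype=np.int8))
        freq, derived, called = qc.allele_frequency(cohort, 0)
        assert (derived, called) == (3, 4)

    def test_derived_on_reference_orientation(self):
        v = VariantRecord("chr1", 10, "A", "G", derived_is_alt=False)
        cohort = Cohort(variants=[v], samples=["a", "b"],
                        genotypes=np.array([[0], [1]], dtype=np.int8))
        freq, derived, called = qc.allele_frequency(cohort, 0)
        assert (derived, called) == (3, 4)  # 2 + 1 reference(=derived) alleles

    def test_all_missing_rejected(self):
        cohort = tiny_cohort(np.array([[-1], [-1]], dtype=np.int8))
        with pytest.raises(ValueError):
            qc.allele_frequency(cohort, 0)

    def test_invariant_to_individual_order(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, (30, 1)).astype(np.int8)
        cohort = tiny_cohort(g)
        shuffled = cohort.subset_samples(rng.permutation(30))
        assert qc.allele_frequency(cohort, 0) == qc.allele_frequency(shuffled, 0)


def hwe_oracle(hom_ref: int, het: int, hom_alt: int) -> Fraction:
    """Exact-rational enumeration of the conditional heterozygote distribution."""
    n = hom_ref + het + hom_alt
    m = min(2 * hom_ref + het, 2 * hom_alt + het)
    if m == 0:
        return Fraction(1)
    probs = {}
    for h in range(m % 2, m + 1, 2):
        ha = (m - h) // 2
        hr = n - h - ha
        if hr < 0:
            continue
        ways = (
            Fraction(comb(n, ha)) * comb(n - ha, h) * 2**h
        )
        probs[h] = ways
    total = sum(probs.values())
    p_obs = probs[het]
    return sum(p for p in probs.values() if p <= p_obs) / total


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert qc.hwe_exact_test(0, 0, 37) == 1.0
        assert qc.hwe_exact_test(37, 0, 0) == 1.0

    def test_modal_configuration_is_one(self):
        assert qc.hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_deficit_tiny_p(self):
        assert qc.hwe_exact_test(50, 0, 50) < 1e-20

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 2, 3)

    def test_matches_rational_enumeration_exhaustively(self):
        # every (N <= 50, minor-allele-count, het) configuration
        for n in range(1, 51):
            for m in range(0, n + 1):
                for het in range(m % 2, m + 1, 2):
                    ha = (m - het) // 2
                    hr = n - het - ha
                    if hr < 0:
                        continue
                    got = qc.hwe_exact_test(hr, het, ha)
                    want = float(hwe_oracle(hr, het, ha))
                    assert got == pytest.approx(want, rel=1e-9), (n, m, het)

    def test_symmetric_in_allele_labels(self):
        assert qc.hwe_exact_test(30, 15, 5) == pytest.approx(
            qc.hwe_exact_test(5, 15, 30))


class TestConcordance:
    def _pair(self, g_a, g_b, classes):
        a = tiny_cohort(g_a)
        b = Cohort(variants=list(a.variants), samples=list(a.samples),
                   genotypes=np.asarray(g_b, dtype=np.int8))
        return a, b, classes

    def test_identical_cohorts_full_concordance(self):
        g = np.array([[0, 1], [2, 1]], dtype=np.int8)
        a, b, _ = self._pair(g, g, None)
        keys = [v.key for v in a.variants]
        rates = qc.concordance(a, b, {"exonic": keys})
        assert rates["exonic"] == 1.0

    def test_partial_mismatch_rate(self):
        # 100 intronic genotype pairs with exactly 23 mismatching
        rng = np.random.default_rng(3)
        g_a = rng.integers(0, 3, (10, 10)).astype(np.int8)
        g_b = g_a.copy()
        flat = rng.choice(100, size=23, replace=False)
        for k in flat:
            i, j = divmod(k, 10)
            g_b[i, j] = (g_a[i, j] + 1) % 3
        a, b, _ = self._pair(g_a, g_b, None)
        rates = qc.concordance(a, b, {"intronic": [v.key for v in a.variants]})
        assert rates["intronic"] == pytest.approx(0.77)

    def test_disjoint_variants_rejected(self):
        a = tiny_cohort(np.zeros((2, 2), dtype=np.int8))
        b = Cohort(variants=make_variants(2, start=99999),
                   samples=list(a.samples),
                   genotypes=np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            qc.concordance(a, b, {"exonic": []})


class TestIbsMds:
    def test_duplicate_individuals_coincide(self):
        g = np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0], [2, 1, 0]],
                     dtype=np.int8)
        cohort = tiny_cohort(g)
        d = qc.ibs_distance_matrix(cohort)
        assert d[0, 1] == 0.0
        coords = qc.ibs_mds(cohort)
        assert np.allclose(coords[0], coords[1])
        assert np.allclose(coords[2], coords[3])

    def test_two_fixed_clusters_separate_on_axis_one(self):
        g = np.array([[0] * 10, [0] * 10, [2] * 10, [2] * 10], dtype=np.int8)
        coords = qc.ibs_mds(tiny_cohort(g))
        # within-cluster identical, between-cluster split on axis 1
        assert np.allclose(coords[0, 0], coords[1, 0])
        assert abs(coords[0, 0] - coords[2, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            qc.ibs_mds(tiny_cohort(np.zeros((2, 3), dtype=np.int8)))


class TestAncestryOutliers:
    @staticmethod
    def _mixture_scenario():
        recs = make_variants(60)
        rng = np.random.default_rng(42)
        pa = rng.uniform(0.0, 0.15, 60)
        pb = rng.uniform(0.85, 1.0, 60)
        spec_a = synthdata.CohortSpec(104, list(zip(recs, pa)),
                                      "hwe_sampling", seed=1, sample_prefix="A")
        spec_b = synthdata.CohortSpec(60, list(zip(recs, pb)),
                                      "hwe_sampling", seed=2, sample_prefix="B")
        pooled = Cohort.concatenate([
            synthdata.simulate_cohort(spec_a),
            synthdata.simulate_cohort(spec_b),
            synthdata.simulate_admixed(spec_a, spec_b, 0.5, 9, seed=3),
        ])
        labels = ["A"] * 104 + ["B"] * 60 + ["A"] * 9
        return pooled, labels

    def test_all_at_medoid_none_flagged(self):
        coords = np.zeros((6, 2))
        assert not qc.flag_ancestry_outliers(coords, ["A"] * 6).any()

    def test_infinite_k_flags_nothing(self):
        pooled, labels = self._mixture_scenario()
        coords = qc.ibs_mds(pooled)
        assert not qc.flag_ancestry_outliers(coords, labels, k=np.inf).any()

    def test_planted_admixed_individuals_flagged(self):
        # half-and-half genomes claiming the first cluster must be caught
        pooled, labels = self._mixture_scenario()
        coords = qc.ibs_mds(pooled)
        # admixed individuals land between the two clusters on axis 1
        a_mean = coords[:104, 0].mean()
        b_mean = coords[104:164, 0].mean()
        adx = coords[164:, 0].mean()
        assert min(a_mean, b_mean) < adx < max(a_mean, b_mean)
        flags = qc.flag_ancestry_outliers(coords, labels)
        assert flags[164:].all()
        assert flags.sum() == 9

    def test_small_cluster_rejected(self):
        with pytest.raises(ValueError):
            qc.flag_ancestry_outliers(np.zeros((4, 2)), ["A", "A", "B", "B"])
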