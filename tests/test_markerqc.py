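"""Marker filters, segregation typing and the exact Hardy-Weinberg test."""

import numpy as np
import pytest

from scafmap.markerqc import (
    ClassificationError,
    SegregationType,
    classify_segregation,
    exclude_high_missing_samples,
    filter_cross_markers,
    filter_ld_markers,
    hwe_exact_test,
    prune_redundant,
)
from scafmap.matrix import MISSING


class TestClassifySegregation:
    def test_dominant_types(self):
        assert classify_segregation(1, 0, {0: 47, 1: 47}) == SegregationType.D1_10
        assert classify_segregation(0, 1, {0: 47, 1: 47}) == SegregationType.D2_15
        assert classify_segregation(1, 1, {0: 24, 1: 48, 2: 22}) == SegregationType.B3_7
        assert classify_segregation(0, 0, {0: 94}) == SegregationType.UNINFORMATIVE

    def test_null_allele_b1_5(self):
        # A het, B called hom-ref, but hom-alt offspring appear at a 2:1:1 fit
        assert classify_segregation(1, 0, {0: 48, 1: 24, 2: 22}) == SegregationType.B1_5

    def test_null_allele_b2_6(self):
        # B het, A called hom-ref but really null-het: hom-alt offspring
        # appear and counts fit the 2:1:1 null expectation
        assert classify_segregation(0, 1, {0: 48, 1: 24, 2: 22}) == SegregationType.B2_6

    def test_impossible_class_without_null_fit_stays_dominant(self):
        # a lone impossible genotype that does not fit 2:1:1 is not a null
        assert classify_segregation(1, 0, {0: 46, 1: 47, 2: 1}) == SegregationType.D1_10

    def test_double_null_c8(self):
        # both parents hom for the same allele, 3:1 called-to-dropout
        assert (
            classify_segregation(0, 0, {0: 72, MISSING: 24}) == SegregationType.C_8
        )

    def test_both_parents_missing_raises(self):
        with pytest.raises(ClassificationError):
            classify_segregation(MISSING, None, {0: 10})


class TestCrossFilter:
    def test_nine_per_class_rejected(self, matrix_factory):
        g = [[0] * 9 + [1] * 85]
        out = filter_cross_markers(matrix_factory(g))
        assert out.n_markers == 0

    def test_ten_per_class_with_30pct_lowq_retained(self, matrix_factory):
        # 100 samples: 30 low-quality (recoded missing), 70 calls split 10/60
        g = [[0] * 10 + [1] * 60 + [1] * 30]
        q = [[60] * 70 + [10] * 30]
        out = filter_cross_markers(matrix_factory(g, q))
        assert out.n_markers == 1
        assert (out.genotypes[0, 70:] == MISSING).all()

    def test_31pct_lowq_rejected(self, matrix_factory):
        g = [[0] * 10 + [1] * 59 + [1] * 31]
        q = [[60] * 69 + [10] * 31]
        assert filter_cross_markers(matrix_factory(g, q)).n_markers == 0

    def test_idempotent(self, matrix_factory, rng):
        g = rng.integers(0, 3, size=(50, 94)).astype(np.int8)
        q = rng.integers(5, 61, size=(50, 94)).astype(np.int16)
        once = filter_cross_markers(matrix_factory(g, q))
        twice = filter_cross_markers(once)
        assert twice.equals(once)


class TestSampleExclusion:
    def test_strict_majority_boundary(self, matrix_factory):
        g = np.ones((100, 2), dtype=np.int8)
        g[:51, 0] = MISSING  # 51% missing
        g[:50, 1] = MISSING  # 50% missing
        out, excluded = exclude_high_missing_samples(matrix_factory(g))
        assert excluded == ["s0"]
        assert out.samples == ["s1"]

    def test_all_excluded_raises(self, matrix_factory):
        g = np.full((10, 2), MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            exclude_high_missing_samples(matrix_factory(g))


def _hwe_oracle(n_hom_ref, n_het, n_hom_alt):
    """Independent recurrence-based enumeration of the exact HWE test."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    hets = list(range(rare % 2, rare + 1, 2))
    probs = {hets[0]: 1.0}
    # ratio P(h+2)/P(h) = 4 * n_hom_r(h) * n_hom_a(h) / ((h+2)(h+1))
    for h in hets[:-1]:
        hom_r = (n_a - h) // 2
        hom_a = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_a / ((h + 2.0) * (h + 1.0))
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return min(1.0, sum(v / total for v in probs.values() if v / total <= p_obs * (1 + 1e-12)))


class TestHWE:
    def test_equilibrium_counts_accepted(self):
        assert hwe_exact_test(25, 50, 25) > 0.001

    def test_heterozygote_deficit_rejected(self):
        assert hwe_exact_test(48, 0, 48) < 0.001

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 96) == 1.0
        assert hwe_exact_test(96, 0, 0) == 1.0

    def test_against_recurrence_oracle_sample(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 200))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = n - a - b
            assert hwe_exact_test(a, b, c) == pytest.approx(_hwe_oracle(a, b, c), abs=1e-12)

    def test_allele_label_symmetry(self, rng):
        for _ in range(50):
            a, b, c = rng.integers(0, 40, size=3)
            assert hwe_exact_test(a, b, c) == pytest.approx(hwe_exact_test(c, b, a), abs=1e-12)


class TestLDFilter:
    def test_19_per_class_rejected_20_retained(self, matrix_factory):
        # two-class markers at the 20-individual boundary (in HW proportions)
        g19 = [[0] * 77 + [1] * 19]
        g20 = [[0] * 76 + [1] * 20]
        assert filter_ld_markers(matrix_factory(g19)).n_markers == 0
        assert filter_ld_markers(matrix_factory(g20)).n_markers == 1

    def test_hwe_failure_rejected(self, matrix_factory):
        g = [[0] * 48 + [2] * 48]  # no heterozygotes at p = 0.5
        assert filter_ld_markers(matrix_factory(g)).n_markers == 0

    def test_phred_between_3_and_15_kept_as_call(self, matrix_factory):
        g = [[0] * 30 + [1] * 40 + [2] * 26]
        q = [[7] * 20 + [60] * 76]
        out = filter_ld_markers(matrix_factory(g, q))
        assert out.n_markers == 1
        assert (out.genotypes[0, :20] != MISSING).all()

    def test_phred_below_3_set_missing(self, matrix_factory):
        g = [[0] * 30 + [1] * 40 + [2] * 26]
        q = [[2] * 5 + [60] * 91]
        out = filter_ld_markers(matrix_factory(g, q))
        assert (out.genotypes[0, :5] == MISSING).all()

    def test_below_70pct_good_quality_rejected(self, matrix_factory):
        g = [[0] * 30 + [1] * 40 + [2] * 26]
        q = [[10] * 30 + [60] * 66]  # only 68.75% at Phred >= 15
        assert filter_ld_markers(matrix_factory(g, q)).n_markers == 0

    def test_wholegenome_extras(self, matrix_factory):
        import pandas as pd

        hwe_ok = [0] * 24 + [1] * 48 + [2] * 24
        g = [hwe_ok] * 4
        m = matrix_factory(
            g,
            scaffolds=["S1", "S1", "S2", "S3"],
            positions=[100, 200, 150, 150],
            is_indel=[False, True, True, False],
        )
        probes = pd.DataFrame({"scaffold_id": ["S3"], "start": [120], "end": [180]})
        out = filter_ld_markers(
            m, mode="wholegenome", probe_intervals=probes, unique_scaffolds=["S1", "S2", "S3"]
        )
        kept = set(out.markers["marker_id"])
        # S1 indel dropped (scaffold has a SNP); S2 indel kept (SNP-free
        # scaffold); S3 SNP dropped (probe-covered)
        assert kept == {"m0", "m2"}

    def test_non_unique_scaffold_dropped(self, matrix_factory):
        import pandas as pd

        g = [[0] * 24 + [1] * 48 + [2] * 24]
        m = matrix_factory(g, scaffolds=["S9"])
        out = filter_ld_markers(
            m, mode="wholegenome",
            probe_intervals=pd.DataFrame(columns=["scaffold_id", "start", "end"]),
            unique_scaffolds=["S1"],
        )
        assert out.n_markers == 0

    def test_wholegenome_requires_inputs(self, matrix_factory):
        with pytest.raises(ValueError):
            filter_ld_markers(matrix_factory([[0, 1]]), mode="wholegenome")


class TestPrune:
    def test_seven_differences_dropped_eight_kept(self, matrix_factory):
        base = np.zeros(96, dtype=np.int8)
        seven = base.copy(); seven[:7] = 1
        eight = base.copy(); eight[:8] = 1
        m = matrix_factory([base, seven, eight], positions=[1, 2, 3])
        out = prune_redundant(m)
        assert list(out.markers["marker_id"]) == ["m0", "m2"]

    def test_identical_markers_on_different_scaffolds_kept(self, matrix_factory):
        base = np.zeros(96, dtype=np.int8)
        m = matrix_factory([base, base], scaffolds=["S1", "S2"], positions=[1, 1])
        assert prune_redundant(m).n_markers == 2

    def test_missing_vs_called_counts_as_difference(self, matrix_factory):
        base = np.zeros(96, dtype=np.int8)
        other = base.copy(); other[:8] = MISSING
        m = matrix_factory([base, other], positions=[1, 2])
        assert prune_redundant(m).n_markers == 2

    def test_retained_set_pairwise_property_and_idempotence(self, matrix_factory, rng):
        g = rng.integers(0, 3, size=(40, 50)).astype(np.int8)
        m = matrix_factory(g, scaffolds=["S1"] * 40, positions=list(range(1, 41)))
        out = prune_redundant(m)
        gg = out.genotypes
        for i in range(out.n_markers):
            for j in range(i + 1, out.n_markers):
                assert (gg[i] != gg[j]).sum() >= 8
        assert prune_redundant(out).equals(out)
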