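import numpy as np
import pytest

from aluwave.discriminant import (
    ClassifyingRegion,
    CoefficientScore,
    CohortCoefficients,
    DiscriminantConfig,
    discriminant_score,
    global_classifying_regions,
    pair_variability,
    refine_to_smallest_scale,
    score_rows,
    select_coefficients,
)
from aluwave.wpt import CoefficientIndex, haar_wpt_forward

from conftest import cohort_from_positions, single_peak_cohort


class TestPairVariability:
    def test_identical_tables_give_zero(self):
        t = haar_wpt_forward(np.arange(16.0))
        for row in pair_variability(t, t):
            assert not row.any()

    def test_absolute_difference(self):
        tx = haar_wpt_forward(np.array([2.0, 0, 0, 0]))
        ty = haar_wpt_forward(np.array([0.5, 0, 0, 0]))
        np.testing.assert_allclose(pair_variability(tx, ty)[0][0], 1.5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        tx = haar_wpt_forward(rng.normal(size=32))
        ty = haar_wpt_forward(rng.normal(size=32))
        for a, b in zip(pair_variability(tx, ty), pair_variability(ty, tx)):
            np.testing.assert_array_equal(a, b)


class TestScore:
    def test_identical_cohort_scores_zero(self, identical_cohort):
        rows = score_rows(identical_cohort, 1)
        for row in rows.values():
            np.testing.assert_allclose(row, 0.0, atol=1e-12)
        assert select_coefficients(identical_cohort, 1) == []

    def test_twin_swap_invariance(self):
        pos = {
            (1, "a"): [300.0], (1, "b"): [301.5],
            (2, "a"): [310.0], (2, "b"): [312.0],
            (3, "a"): [320.0], (3, "b"): [320.0],
        }
        base = cohort_from_positions(pos)
        swapped = cohort_from_positions(
            {**pos, (2, "a"): pos[(2, "b")], (2, "b"): pos[(2, "a")]}
        )
        for j, row in score_rows(base, 1).items():
            np.testing.assert_allclose(row, score_rows(swapped, 1)[j], atol=1e-12)

    def test_nonreference_couple_permutation_invariance(self):
        pos = {
            (1, "a"): [300.0], (1, "b"): [300.0],
            (2, "a"): [310.0], (2, "b"): [311.0],
            (3, "a"): [500.0], (3, "b"): [500.0],
        }
        base = cohort_from_positions(pos)
        permuted = cohort_from_positions(
            {
                (1, "a"): pos[(1, "a")], (1, "b"): pos[(1, "b")],
                (2, "a"): pos[(3, "a")], (2, "b"): pos[(3, "b")],
                (3, "a"): pos[(2, "a")], (3, "b"): pos[(2, "b")],
            }
        )
        for j, row in score_rows(base, 1).items():
            np.testing.assert_allclose(row, score_rows(permuted, 1)[j], atol=1e-12)

    def test_shared_peak_creates_no_selection(self):
        """Content common to all six signals is contrast-free: adding a
        shared peak anywhere yields an empty selection."""
        pos = {(k, t): [250.0, 251.0, 600.0] for k in (1, 2, 3) for t in "ab"}
        assert select_coefficients(cohort_from_positions(pos), 1) == []

    def test_presence_absence_scores_exactly_one(self):
        cohort = single_peak_cohort(500.0, None)
        best = max(s.K for s in select_coefficients(cohort, 1))
        assert best == pytest.approx(1.0, abs=1e-6)

    def test_displaced_single_peak_scores_near_one(self):
        """A single peak at couple-distinct positions within one support
        (opposite-sign / near-zero coefficients) gives K close to 1."""
        pos = {
            (1, "a"): [394.0], (1, "b"): [394.0],
            (2, "a"): [398.0], (2, "b"): [398.0],
            (3, "a"): [396.0], (3, "b"): [396.0],
        }
        cohort = cohort_from_positions(pos)
        best = max(s.K for s in select_coefficients(cohort, 1))
        assert 0.8 <= best <= 1.2

    def test_within_couple_variability_cancels_equal_cross_contrast(self):
        """If the within-couple difference equals the smallest cross-couple
        difference, the two criterion terms cancel and K <= 0 there."""
        pos = {
            (1, "a"): [500.0], (1, "b"): [503.0],
            (2, "a"): [503.0], (2, "b"): [503.0],
            (3, "a"): [503.0], (3, "b"): [503.0],
        }
        rows = score_rows(cohort_from_positions(pos), 1)
        assert max(row.max() for row in rows.values()) <= 1e-9

    def test_selection_monotone_in_delta(self):
        cohort = single_peak_cohort(500.0, 505.0)
        sizes = [
            len(select_coefficients(cohort, 1, DiscriminantConfig(delta=d)))
            for d in (0.2, 1 / 3, 0.6, 1.2)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_moderate_selection_count_for_one_polymorphism(self):
        """One polymorphic locus lights up on the order of ten coefficients
        across the nested scales (the multiscale redundancy)."""
        cohort = single_peak_cohort(500.0, 508.0)
        n = len(select_coefficients(cohort, 1))
        assert 3 <= n <= 120

    def test_selected_supports_contain_the_polymorphism(self):
        cohort = single_peak_cohort(500.0, 503.0)
        scores = select_coefficients(cohort, 1)
        assert scores
        for s in scores:
            lo, hi = s.support_bp()
            assert lo <= 503.0 + 5 and hi >= 500.0 - 5

    def test_single_score_wrapper_and_errors(self, identical_cohort):
        idx = CoefficientIndex(8, 0, 0)
        assert discriminant_score(identical_cohort, 1, idx) == 0.0
        with pytest.raises(ValueError):
            discriminant_score(identical_cohort, 5, idx)
        with pytest.raises(ValueError):
            discriminant_score(identical_cohort, 1, CoefficientIndex(2, 0, 0))

    def test_delta_zero_rejected(self):
        with pytest.raises(ValueError):
            DiscriminantConfig(delta=0.0)

    def test_incomplete_cohort_rejected(self):
        t = haar_wpt_forward(np.zeros(64))
        with pytest.raises(ValueError, match="incomplete"):
            CohortCoefficients(tables={(1, "a"): t})


class TestRefinement:
    def score(self, depth, block, translation, K):
        return CoefficientScore(1, CoefficientIndex(depth, block, translation), K)

    def test_nested_chain_keeps_smallest_support(self):
        chain = [self.score(10, 0, 0, 0.9), self.score(9, 0, 0, 0.8),
                 self.score(8, 0, 1, 0.7)]
        kept = refine_to_smallest_scale(chain)
        assert len(kept) == 1 and kept[0].idx.depth == 8

    def test_disjoint_supports_both_kept(self):
        kept = refine_to_smallest_scale(
            [self.score(8, 0, 0, 0.9), self.score(8, 0, 5, 0.8)]
        )
        assert len(kept) == 2

    def test_single_selection_unchanged(self):
        s = self.score(9, 1, 2, 0.5)
        assert refine_to_smallest_scale([s]) == [s]

    def test_tie_on_support_prefers_larger_K_then_lower_block(self):
        kept = refine_to_smallest_scale(
            [self.score(8, 3, 0, 0.5), self.score(8, 1, 0, 0.9),
             self.score(8, 2, 0, 0.9)]
        )
        assert len(kept) == 1 and kept[0].idx.block == 1

    def test_mixed_reference_couples_rejected(self):
        bad = [self.score(8, 0, 0, 0.5),
               CoefficientScore(2, CoefficientIndex(8, 0, 1), 0.5)]
        with pytest.raises(ValueError):
            refine_to_smallest_scale(bad)


class TestGlobalRegions:
    def test_no_polymorphism_no_regions(self, identical_cohort):
        assert global_classifying_regions(identical_cohort) == []

    def test_single_pairwise_distinct_locus_yields_one_region(self):
        pos = {
            (1, "a"): [500.0], (1, "b"): [500.0],
            (2, "a"): [508.0], (2, "b"): [508.0],
            (3, "a"): [516.0], (3, "b"): [516.0],
        }
        regions = global_classifying_regions(cohort_from_positions(pos))
        assert len(regions) == 1
        lo, hi = regions[0].merged_interval()
        assert lo <= 500.0 and hi >= 516.0
        assert all(K >= 1 / 3 for K in regions[0].couple_K.values())

    def test_couple1_only_difference_is_not_global(self):
        """A locus separating couple 1 from the (identical) couples 2 and 3
        classifies for reference couple 1 but is not a global region."""
        cohort = single_peak_cohort(500.0, 508.0)
        assert select_coefficients(cohort, 1)
        assert select_coefficients(cohort, 2) == []
        assert global_classifying_regions(cohort) == []

    def test_regions_sorted_and_channel_tagged(self):
        pos = {
            (1, "a"): [200.0, 700.0], (1, "b"): [200.0, 700.0],
            (2, "a"): [208.0, 708.0], (2, "b"): [208.0, 708.0],
            (3, "a"): [216.0, 716.0], (3, "b"): [216.0, 716.0],
        }
        regions = global_classifying_regions(cohort_from_positions(pos))
        assert len(regions) == 2
        assert regions[0].merged_interval() < regions[1].merged_interval()
        assert all(r.channel == "x" for r in regions)
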