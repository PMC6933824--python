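import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import assert_matches_printed
from trophomito import datasets
from trophomito.differential import (
    TestConfig,
    assign_pathways,
    classify_direction,
    log2_fold_change,
    pseudocount_ratio,
    round_half_up,
    run_differential,
    summarize_directions,
)
from trophomito.errors import ValidationError
from trophomito.types import AnnotatedCounts, Direction, ProteinCounts


def annotated_protein(gene, c, s, mito=True):
    record = ProteinCounts(
        protein_id=f"ID_{gene}",
        gene=gene,
        group_counts={"cyto_mito": float(c), "syncytio_mito": float(s)},
    )
    return AnnotatedCounts(
        record=record, is_mitochondrial=mito, matched_symbol=gene if mito else None
    )


positive_counts = st.floats(0, 1e4, allow_nan=False, allow_infinity=False)


class TestPseudocountRatio:
    @pytest.mark.parametrize(
        "c, s, kappa, expected",
        [
            (232, 136, 1, "1.70073"),  # ATP synthase beta, the largest count pair
            (7, 0, 1, "8"),  # PEPCK-M: zero in one group stays finite
            (0.171777, 0.036219, 0, "4.74273091"),  # plain-ratio dialect on TPM
            (93, 129, 1, "0.723077"),  # higher in syncytiotrophoblast
        ],
    )
    def test_published_values(self, c, s, kappa, expected):
        assert_matches_printed(pseudocount_ratio(c, s, kappa), expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(x=positive_counts, kappa=st.floats(0.01, 10))
    def test_equal_counts_give_unit_ratio(self, x, kappa):
        assert pseudocount_ratio(x, x, kappa) == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(c=positive_counts, s=positive_counts, kappa=st.floats(0.01, 10))
    def test_reciprocal_symmetry(self, c, s, kappa):
        forward = pseudocount_ratio(c, s, kappa)
        backward = pseudocount_ratio(s, c, kappa)
        assert forward * backward == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(c=positive_counts, s=positive_counts, kappa=st.floats(0.01, 10))
    def test_strictly_monotone_in_each_count(self, c, s, kappa):
        base = pseudocount_ratio(c, s, kappa)
        assert pseudocount_ratio(c + 1, s, kappa) > base
        assert pseudocount_ratio(c, s + 1, kappa) < base

    def test_zero_pseudocount_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            pseudocount_ratio(5, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            pseudocount_ratio(-1, 2, 1)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "ratio, expected", [(8, "3"), (1, "0"), (1.70073, "0.766154")]
    )
    def test_published_values(self, ratio, expected):
        assert_matches_printed(log2_fold_change(ratio), expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(c=positive_counts, s=positive_counts)
    def test_antisymmetric_under_group_swap(self, c, s):
        forward = log2_fold_change(pseudocount_ratio(c, s, 1))
        backward = log2_fold_change(pseudocount_ratio(s, c, 1))
        assert forward == pytest.approx(-backward, abs=1e-9)

    @pytest.mark.parametrize("ratio", [0, -1])
    def test_nonpositive_ratio_rejected(self, ratio):
        with pytest.raises(ValidationError):
            log2_fold_change(ratio)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "ratio, tolerance, expected",
        [
            (1.70073, 0, Direction.HIGHER_GROUP1),
            (1.0, 0, Direction.UNCHANGED),
            (0.723077, 0, Direction.HIGHER_GROUP2),
            (1.05, 0.1, Direction.UNCHANGED),
            (1.0 / 1.05, 0.1, Direction.UNCHANGED),
            (1.2, 0.1, Direction.HIGHER_GROUP1),
        ],
    )
    def test_classification(self, ratio, tolerance, expected):
        assert classify_direction(ratio, tolerance) is expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ratio=st.floats(0.01, 100), tolerance=st.floats(0, 1))
    def test_band_is_multiplicatively_symmetric(self, ratio, tolerance):
        forward = classify_direction(ratio, tolerance)
        backward = classify_direction(1.0 / ratio, tolerance)
        assert forward.sign == -backward.sign


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "value, expected", [(2.5, 3), (2.49, 2), (0.5, 1), (3.0, 3), (0.0, 0)]
    )
    def test_half_up(self, value, expected):
        assert round_half_up(value) == expected


class TestRunDifferential:
    def test_reproduces_every_published_ratio_and_fold_change(
        self, differential_results
    ):
        printed = datasets.load_printed_differential()
        assert len(differential_results) == 29
        by_gene = {res.gene: res for res in differential_results}
        for row in printed.itertuples(index=False):
            result = by_gene[row.gene]
            assert_matches_printed(result.ratio, row.ratio)
            assert_matches_printed(result.log2fc, row.log2fc)

    def test_identification_filter_uses_maximum_group_count(self):
        # 7-vs-0 passes (max 7 >= 3); 2-vs-2 fails (max 2 < 3)
        results = run_differential(
            [annotated_protein("KEEP", 7, 0), annotated_protein("DROP", 2, 2)]
        )
        assert [res.gene for res in results] == ["KEEP"]

    def test_single_low_count_protein_filtered_to_empty(self):
        assert run_differential([annotated_protein("G", 2, 2)]) == []

    def test_non_mitochondrial_records_excluded(self):
        results = run_differential(
            [annotated_protein("MITO", 20, 10), annotated_protein("ACTB", 30, 30, mito=False)]
        )
        assert [res.gene for res in results] == ["MITO"]

    def test_output_preserves_input_order(self, differential_results, count_records):
        assert [res.protein_id for res in differential_results] == [
            rec.protein_id for rec in count_records
        ]

    def test_significance_consistent_with_alpha(self, differential_results):
        for res in differential_results:
            assert res.significant == (res.p_value <= 0.05)
            assert 0.0 <= res.p_value <= 1.0

    def test_explicit_totals_must_cover_counts(self):
        config = TestConfig(background_mode="explicit", explicit_totals=(10, 10))
        with pytest.raises(ValidationError):
            run_differential([annotated_protein("G", 20, 5)], config)

    def test_explicit_totals_used_for_background(self):
        config = TestConfig(background_mode="explicit", explicit_totals=(5000, 3500))
        [res] = run_differential([annotated_protein("ATP5B", 232, 136)], config)
        from trophomito.differential import fisher_background_test

        assert res.p_value == fisher_background_test(232, 136, 5000, 3500)

    def test_q_values_attached_and_bounded(self, annotated):
        results = run_differential(annotated, TestConfig(compute_q_values=True))
        for res in results:
            assert res.q_value is not None
            assert res.p_value <= res.q_value <= 1.0


class TestSummaries:
    def test_direction_partition_of_published_table(self, differential_results):
        assert summarize_directions(differential_results) == (24, 0, 5)

    def test_empty_input(self):
        assert summarize_directions([]) == (0, 0, 0)

    def test_order_invariance(self, differential_results):
        shuffled = list(differential_results)
        random.Random(0).shuffle(shuffled)
        assert summarize_directions(shuffled) == summarize_directions(
            differential_results
        )

    def test_triple_sums_to_input_length(self, differential_results):
        assert sum(summarize_directions(differential_results)) == len(
            differential_results
        )


class TestAssignPathways:
    def test_published_pathway_blocks(self, differential_results):
        counts = assign_pathways(
            differential_results, datasets.load_pathway_map("blocks")
        )
        assert counts["Carbohydrate metabolism"] == 3  # PCK2, PC, PDPR
        assert counts["Fatty acid metabolism"] == 2  # LRPPRC, ACADVL
        assert sum(counts.values()) == len(differential_results)

    def test_functional_category_variant_leaves_vdac_unassigned(
        self, differential_results
    ):
        counts = assign_pathways(
            differential_results, datasets.load_pathway_map("functional")
        )
        assert counts["Pyruvate metabolism"] == 3
        assert counts["unassigned"] == 2  # the two VDAC channels
        assert sum(counts.values()) == len(differential_results)

    def test_empty_input(self):
        assert assign_pathways([], {"A": "x"}) == {}
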