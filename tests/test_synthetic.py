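import math

import numpy as np
import pytest

from trophomito.concordance import match_directions, summarize_concordance
from trophomito.differential import TestConfig
from trophomito.errors import ValidationError
from trophomito.synthetic import (
    FoldChangeSpec,
    SimulatedTruth,
    SimulationConfig,
    as_annotated,
    evaluate_operating_characteristics,
    simulate_expression_tables,
    simulate_peptide_counts,
)
from trophomito.types import Direction, DifferentialResult, Stage

GROUPS = ("cyto_mito", "syncytio_mito")


def config(**kwargs):
    return SimulationConfig(**{"n_proteins": 200, "seed": 42, **kwargs})


class TestSimulatePeptideCounts:
    def test_same_seed_is_bit_identical(self):
        first_records, first_truth = simulate_peptide_counts(config())
        second_records, second_truth = simulate_peptide_counts(config())
        assert first_records == second_records
        assert np.array_equal(first_truth.fold_change, second_truth.fold_change)
        assert np.array_equal(first_truth.is_de, second_truth.is_de)

    def test_different_seeds_differ(self):
        first, _ = simulate_peptide_counts(config(seed=1))
        second, _ = simulate_peptide_counts(config(seed=2))
        assert first != second

    def test_null_configuration_plants_nothing(self):
        _, truth = simulate_peptide_counts(config(de_fraction=0.0))
        assert not truth.is_de.any()
        assert (truth.fold_change == 1.0).all()

    def test_group_means_equal_replicate_means(self):
        records, _ = simulate_peptide_counts(config())
        for rec in records:
            for group in GROUPS:
                runs = rec.replicate_counts[group]
                assert rec.group_counts[group] == pytest.approx(
                    sum(runs) / len(runs)
                )

    def test_planted_fold_change_recovered_in_count_ratios(self):
        """Law-of-large-numbers check on the generator: with a fixed planted
        fold of 4 (all up) and deep counts, the mean per-protein count ratio
        among planted proteins approaches 4."""
        sim = config(
            n_proteins=1000,
            de_fraction=0.2,
            fold_changes=FoldChangeSpec(fixed=4.0),
            de_up_fraction=1.0,
            depth={GROUPS[0]: 50000.0, GROUPS[1]: 50000.0},
            seed=7,
        )
        records, truth = simulate_peptide_counts(sim)
        ratios = np.array(
            [
                rec.group_counts[GROUPS[0]] / rec.group_counts[GROUPS[1]]
                for rec, de in zip(records, truth.is_de)
                if de and rec.group_counts[GROUPS[1]] > 0
            ]
        )
        se = ratios.std(ddof=1) / math.sqrt(ratios.size)
        assert abs(ratios.mean() - 4.0) <= 3 * se + 0.05  # small Jensen bias allowance

    def test_expected_run_totals_match_depth(self):
        sim = config(n_proteins=500, de_fraction=0.0, seed=3)
        records, _ = simulate_peptide_counts(sim)
        for group in GROUPS:
            total = sum(rec.group_counts[group] for rec in records)
            # mean of 3 replicate run totals, each Poisson with mean 5000
            assert total == pytest.approx(5000.0, abs=3 * math.sqrt(5000 / 3))

    def test_overdispersion_inflates_variance(self):
        quiet, _ = simulate_peptide_counts(config(n_proteins=2000, seed=5))
        noisy, _ = simulate_peptide_counts(
            config(n_proteins=2000, seed=5, overdispersion=1.0)
        )

        def replicate_cv(records):
            spreads = []
            for rec in records:
                runs = np.array(rec.replicate_counts[GROUPS[0]])
                if runs.mean() > 5:
                    spreads.append(runs.var() / runs.mean())
            return np.mean(spreads)

        assert replicate_cv(noisy) > 2 * replicate_cv(quiet)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_proteins": 0},
            {"n_replicates": 0},
            {"de_fraction": 1.5},
            {"depth": {GROUPS[0]: 100.0}},
            {"depth": {GROUPS[0]: 100.0, GROUPS[1]: -1.0}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            config(**kwargs)

    def test_fold_change_spec_validation(self):
        with pytest.raises(ValidationError):
            FoldChangeSpec(fixed=None, log_uniform=None)
        with pytest.raises(ValidationError):
            FoldChangeSpec(fixed=0.5)
        with pytest.raises(ValidationError):
            FoldChangeSpec(fixed=2.0, log_uniform=(2.0, 4.0))


def truth_based_results(truth):
    out = []
    for i, gene in enumerate(truth.genes):
        fold = truth.fold_change[i]
        direction = (
            Direction.UNCHANGED
            if fold == 1.0
            else Direction.HIGHER_GROUP1 if fold > 1 else Direction.HIGHER_GROUP2
        )
        out.append(
            DifferentialResult(
                protein_id=truth.protein_ids[i],
                gene=gene,
                c=1,
                s=1,
                ratio=fold,
                log2fc=math.log2(fold),
                p_value=0.01,
                direction=direction,
                significant=True,
            )
        )
    return out


class TestSimulateExpressionTables:
    def test_full_concordance_probability(self):
        sim = config(n_proteins=400, de_fraction=0.5, concordance_prob=1.0)
        _, truth = simulate_peptide_counts(sim)
        tables = simulate_expression_tables(truth, sim)
        de_genes = {truth.genes[i] for i in range(len(truth.genes)) if truth.is_de[i]}
        results = [r for r in truth_based_results(truth) if r.gene in de_genes]
        records = match_directions(
            results, tables[Stage.THIRD_TRIMESTER],
        )
        summary = summarize_concordance(records)
        assert summary.fraction_concordant[Stage.THIRD_TRIMESTER] == 1.0

    def test_half_concordance_probability(self):
        sim = config(n_proteins=2000, de_fraction=1.0, concordance_prob=0.5, seed=9)
        _, truth = simulate_peptide_counts(sim)
        tables = simulate_expression_tables(truth, sim)
        records = match_directions(
            truth_based_results(truth), tables[Stage.FIRST_TRIMESTER]
        )
        summary = summarize_concordance(records)
        fraction = summary.fraction_concordant[Stage.FIRST_TRIMESTER]
        se = math.sqrt(0.25 / len(records))
        assert abs(fraction - 0.5) <= 3 * se

    def test_empty_truth_gives_empty_tables(self):
        truth = SimulatedTruth(
            protein_ids=(), genes=(),
            fold_change=np.array([]), is_de=np.array([], dtype=bool),
        )
        tables = simulate_expression_tables(truth, config())
        assert all(records == [] for records in tables.values())

    def test_transcript_truth_recorded_for_every_gene_and_stage(self):
        sim = config(n_proteins=50)
        _, truth = simulate_peptide_counts(sim)
        simulate_expression_tables(truth, sim)
        assert len(truth.transcript_direction) == 100


class TestOperatingCharacteristics:
    def test_type_i_error_never_anticonservative(self):
        """Fisher on replicate-averaged counts is conservative: the observed
        false-positive rate must not exceed alpha (beyond binomial noise)."""
        oc = evaluate_operating_characteristics(
            config(n_proteins=300, de_fraction=0.0, seed=11),
            TestConfig(alpha=0.05),
            n_sims=20,
        )
        limit = 0.05 + 3 * math.sqrt(0.05 * 0.95 / oc.n_null_tests)
        assert oc.type_i_error <= limit

    def test_power_increases_with_fold_change(self):
        common = dict(n_proteins=300, de_fraction=0.2, seed=13)
        weak = evaluate_operating_characteristics(
            config(fold_changes=FoldChangeSpec(fixed=1.5), **common),
            TestConfig(),
            n_sims=8,
        )
        strong = evaluate_operating_characteristics(
            config(fold_changes=FoldChangeSpec(fixed=8.0), **common),
            TestConfig(),
            n_sims=8,
        )
        assert strong.power > weak.power

    def test_power_increases_with_depth(self):
        common = dict(
            n_proteins=300,
            de_fraction=0.2,
            fold_changes=FoldChangeSpec(fixed=2.0),
            seed=17,
        )
        shallow = evaluate_operating_characteristics(
            config(depth={GROUPS[0]: 1000.0, GROUPS[1]: 1000.0}, **common),
            TestConfig(),
            n_sims=8,
        )
        deep = evaluate_operating_characteristics(
            config(depth={GROUPS[0]: 20000.0, GROUPS[1]: 20000.0}, **common),
            TestConfig(),
            n_sims=8,
        )
        assert deep.power > shallow.power

    def test_tiny_alpha_yields_no_discoveries(self):
        oc = evaluate_operating_characteristics(
            config(n_proteins=200, de_fraction=0.0, seed=19),
            TestConfig(alpha=1e-12),
            n_sims=3,
        )
        assert oc.type_i_error == 0.0

    def test_strong_effects_recovered_without_sign_errors(self):
        oc = evaluate_operating_characteristics(
            config(
                n_proteins=300,
                de_fraction=0.1,
                fold_changes=FoldChangeSpec(fixed=8.0),
                seed=23,
            ),
            TestConfig(),
            n_sims=5,
        )
        assert oc.n_significant_de > 0
        assert oc.sign_error_rate == 0.0
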