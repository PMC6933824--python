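"""Cross-validation of proteomic directions against single-cell TPM tables.

Pairs the proteomic directions from the differential stage with the
packaged first- and third-trimester average-TPM tables (plain ratio in the
first-trimester table, pseudocount 1 in the third-trimester one), writes
the per-gene concordance report, and prints the per-stage match counts and
the conserved-across-gestation gene set.
"""

from pathlib import Path

from trophomito import (
    annotate_mitochondrial,
    datasets,
    match_directions,
    run_differential,
    summarize_concordance,
)
from trophomito.tabular_io import write_concordance_table
from trophomito.types import Stage

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    annotated = annotate_mitochondrial(
        datasets.load_count_table(), datasets.load_annotation()
    )
    results = run_differential(annotated)
    expression = [
        record
        for stage in (Stage.FIRST_TRIMESTER, Stage.THIRD_TRIMESTER)
        for record in datasets.load_expression_table(stage)
    ]
    records = match_directions(results, expression)
    write_concordance_table(records, OUT / "concordance_gestation.tsv")

    summary = summarize_concordance(records)
    for stage in sorted(summary.per_stage_matches, key=lambda s: s.value):
        print(
            f"{stage.value}: {summary.per_stage_matches[stage]} of "
            f"{summary.n_tested[stage]} genes direction-concordant "
            f"({summary.fraction_concordant[stage]:.1%})"
        )
    distinct = {rec.gene for rec in records if rec.concordant}
    print(f"distinct concordant genes across stages: {len(distinct)}")
    print(
        f"conserved across gestation ({len(summary.conserved_genes)}): "
        + ", ".join(sorted(summary.conserved_genes))
    )
    print(f"wrote {OUT / 'concordance_gestation.tsv'}")


if __name__ == "__main__":
    main()
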