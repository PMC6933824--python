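"""Differential abundance of the 29 curated trophoblast mitochondrial proteins.

Runs the full differential stage (mitochondrial annotation, >=3 unique
peptide filter, pseudocount ratios with kappa=1, Fisher's exact test against
the column-total background) on the packaged term-placenta count table and
writes the per-protein report plus direction and pathway summaries under
results/.

Published p-values used an unpublished background (the full ~649-protein
identification universe), so the p column here — computed against the
29-protein column totals — is not comparable to them; ratios, fold changes
and directions are.
"""

from pathlib import Path

from trophomito import (
    annotate_mitochondrial,
    assign_pathways,
    datasets,
    run_differential,
    summarize_directions,
)
from trophomito.tabular_io import write_results_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    counts = datasets.load_count_table()
    annotated = annotate_mitochondrial(counts, datasets.load_annotation())
    results = run_differential(annotated)
    write_results_table(results, OUT / "differential_term_placenta.tsv")

    n_up, n_unchanged, n_down = summarize_directions(results)
    print(f"{len(results)} proteins tested")
    print(
        f"direction partition: {n_up} higher in Cyto-Mito, "
        f"{n_unchanged} unchanged, {n_down} higher in Syncytio-Mito"
    )
    print("pathway membership (table-block labels, all tested proteins):")
    for label, count in sorted(
        assign_pathways(results, datasets.load_pathway_map("blocks")).items()
    ):
        print(f"  {label}: {count}")
    print(f"wrote {OUT / 'differential_term_placenta.tsv'}")


if __name__ == "__main__":
    main()
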