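"""Packaged reference tables.

The raw LC-MS data behind the study are not publicly deposited, so the
package ships the curated protein-level tables instead: averaged
unique-peptide counts for the 29 significantly differential mitochondrial
proteins of term placenta, the matching mitochondrial gene inventory, the
per-stage single-cell TPM tables used for transcriptome cross-validation,
two pathway-label maps, and the published ratio / fold-change strings used
as expected values in the test suite.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .tabular_io import (
    CountTableFormat,
    ExpressionTableFormat,
    read_annotation_table,
    read_expression_table,
    read_pathway_map,
    read_peptide_counts,
)
from .types import (
    DEFAULT_GROUPS,
    AnnotationTable,
    ExpressionRecord,
    ProteinCounts,
    Stage,
)

_STAGE_FILES = {
    Stage.FIRST_TRIMESTER: "tpm_first_trimester.tsv",
    Stage.THIRD_TRIMESTER: "tpm_third_trimester.tsv",
}


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    path = Path(str(resources.files("trophomito") / "data" / name))
    if not path.exists():
        raise FileNotFoundError(f"no packaged data file named {name!r}")
    return path


def count_table_format() -> CountTableFormat:
    """Column mapping for the packaged count table (export-style headers)."""
    return CountTableFormat(
        protein_id_column="Protein ID",
        gene_column="Gene name",
        group_columns={
            DEFAULT_GROUPS[0]: "Average unique peptides Cyto-Mito",
            DEFAULT_GROUPS[1]: "Average unique peptides Syncytio-Mito",
        },
    )


def expression_table_format() -> ExpressionTableFormat:
    """Column mapping for the packaged TPM tables."""
    return ExpressionTableFormat(
        gene_column="Gene",
        tpm_columns={"cytotrophoblast": "CYT", "syncytiotrophoblast": "SYN"},
    )


def load_count_table() -> list[ProteinCounts]:
    """The 29 differentially abundant proteins' averaged unique-peptide counts."""
    return read_peptide_counts(
        data_path("unique_peptides_term_placenta.tsv"), count_table_format()
    )


def load_annotation() -> AnnotationTable:
    """Packaged MitoCarta-style inventory (29 study genes + other entries)."""
    return read_annotation_table(data_path("mitocarta_symbols.tsv"))


def load_expression_table(stage: Stage) -> list[ExpressionRecord]:
    """Per-stage single-cell TPM table (average TPM per cell type)."""
    return read_expression_table(
        data_path(_STAGE_FILES[stage]), stage, expression_table_format()
    )


def load_pathway_map(variant: str = "blocks") -> Mapping[str, str]:
    """Gene -> pathway label map.

    ``"blocks"`` uses the differential tables' section headers;
    ``"functional"`` uses the nine functional categories (which leave the
    two VDAC channels unassigned).
    """
    files = {
        "blocks": "pathway_blocks.tsv",
        "functional": "pathway_functional_categories.tsv",
    }
    if variant not in files:
        raise ValueError(f"unknown pathway map variant {variant!r}")
    return read_pathway_map(data_path(files[variant]))


def load_printed_differential() -> pd.DataFrame:
    """Published ratio / log2 fold-change strings per gene (expected values)."""
    return pd.read_csv(data_path("printed_differential.tsv"), sep="\t", dtype=str)


def load_printed_expression() -> pd.DataFrame:
    """Published TPM ratio / fold-change strings per gene and stage."""
    return pd.read_csv(data_path("printed_expression.tsv"), sep="\t", dtype=str)
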