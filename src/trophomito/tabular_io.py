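"""Reading and writing every tabular artifact the pipeline touches.

All files are tab-separated UTF-8 with one header row.  Column names are
never hard-coded: a small format object maps the pipeline's group / cell-type
labels onto whatever the exporting software called its columns, so
MaxQuant-style exports and plain two-column tables go through the same path.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .annotation import normalize_gene_symbol
from .errors import ConfigurationError, ParseError, ValidationError
from .types import (
    DEFAULT_CELL_TYPES,
    DEFAULT_GROUPS,
    AnnotationTable,
    Direction,
    DifferentialResult,
    ExpressionRecord,
    ProteinCounts,
    Stage,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: significant figures used when printing ratios / fold changes to TSV
TSV_SIGFIGS = 6


@dataclass(frozen=True)
class CountTableFormat:
    """Column mapping for a per-protein unique-peptide count table.

    Exactly one of ``group_columns`` (pre-averaged counts, one column per
    group) or ``replicate_columns`` (several per-run columns per group, which
    are averaged on read) must cover each group label.
    """

    protein_id_column: str = "protein_id"
    gene_column: str = "gene"
    group_columns: Optional[Mapping[str, str]] = None
    replicate_columns: Optional[Mapping[str, Sequence[str]]] = None
    group_labels: tuple[str, str] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        for label in self.group_labels:
            in_groups = self.group_columns is not None and label in self.group_columns
            in_reps = (
                self.replicate_columns is not None and label in self.replicate_columns
            )
            if not (in_groups or in_reps):
                raise ConfigurationError(
                    f"no column mapping for group {label!r}"
                )


@dataclass(frozen=True)
class ExpressionTableFormat:
    """Column mapping for a TPM-per-cell-type expression table."""

    gene_column: str = "gene"
    tpm_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            DEFAULT_CELL_TYPES[0]: "tpm_cyt",
            DEFAULT_CELL_TYPES[1]: "tpm_syn",
        }
    )


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, comment="#", skip_blank_lines=True)
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing required column(s) {missing}; found {list(frame.columns)}"
        )
    return frame


def _cell_to_number(value: object, path: PathLike, row: int, column: str) -> float:
    try:
        number = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ParseError(
            f"{path}, data row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None
    if math.isnan(number):
        raise ParseError(
            f"{path}, data row {row}: missing value in column {column!r}"
        )
    if number < 0:
        raise ParseError(
            f"{path}, data row {row}: negative value {number} in column {column!r}"
        )
    return number


def read_peptide_counts(
    path: PathLike, format_config: Optional[CountTableFormat] = None
) -> list[ProteinCounts]:
    """Read a per-protein unique-peptide count table.

    When replicate columns are configured for a group, the group count is
    their arithmetic mean; otherwise it is taken from the pre-averaged
    column.  Row order is preserved and no row is ever silently dropped.
    """
    fmt = format_config or CountTableFormat()
    required: list[str] = [fmt.protein_id_column, fmt.gene_column]
    for label in fmt.group_labels:
        if fmt.replicate_columns is not None and label in fmt.replicate_columns:
            required.extend(fmt.replicate_columns[label])
        else:
            assert fmt.group_columns is not None
            required.append(fmt.group_columns[label])
    frame = _read_tsv(path, required)

    records: list[ProteinCounts] = []
    seen_ids: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        protein_id = str(row_map[fmt.protein_id_column]).strip()
        if protein_id in seen_ids:
            raise ValidationError(
                f"{path}: duplicate protein_id {protein_id!r} at data row {row_number}"
            )
        seen_ids.add(protein_id)
        gene = str(row_map[fmt.gene_column]).strip()

        group_counts: dict[str, float] = {}
        replicate_counts: dict[str, tuple[int, ...]] = {}
        for label in fmt.group_labels:
            if fmt.replicate_columns is not None and label in fmt.replicate_columns:
                runs = []
                for column in fmt.replicate_columns[label]:
                    value = _cell_to_number(row_map[column], path, row_number, column)
                    if value != int(value):
                        raise ParseError(
                            f"{path}, data row {row_number}: replicate column "
                            f"{column!r} must hold integer counts, got {value}"
                        )
                    runs.append(int(value))
                replicate_counts[label] = tuple(runs)
                group_counts[label] = sum(runs) / len(runs)
            else:
                assert fmt.group_columns is not None
                column = fmt.group_columns[label]
                group_counts[label] = _cell_to_number(
                    row_map[column], path, row_number, column
                )
        records.append(
            ProteinCounts(
                protein_id=protein_id,
                gene=gene,
                group_counts=group_counts,
                replicate_counts=replicate_counts or None,
            )
        )
    return records


def read_expression_table(
    path: PathLike,
    stage: Stage,
    format_config: Optional[ExpressionTableFormat] = None,
) -> list[ExpressionRecord]:
    """Read a TPM table for one gestational stage; gene symbols are normalized."""
    fmt = format_config or ExpressionTableFormat()
    required = [fmt.gene_column, *fmt.tpm_columns.values()]
    frame = _read_tsv(path, required)

    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        gene = normalize_gene_symbol(str(row_map[fmt.gene_column]))
        if gene in seen:
            raise ValidationError(
                f"{path}: duplicate gene {gene!r} within stage {stage.value} "
                f"at data row {row_number}"
            )
        seen.add(gene)
        tpm = {
            cell_type: _cell_to_number(row_map[column], path, row_number, column)
            for cell_type, column in fmt.tpm_columns.items()
        }
        records.append(ExpressionRecord(gene=gene, stage=stage, tpm=tpm))
    return records


def read_annotation_table(path: PathLike) -> AnnotationTable:
    """Read a plain-text annotation list: one symbol plus optional
    comma-separated synonyms per line; ``#`` starts a comment."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"annotation file not found: {path}")
    entries: list[tuple[str, tuple[str, ...]]] = []
    with path.open(encoding="utf-8") as handle:
        for line_number, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            symbol = normalize_gene_symbol(fields[0])
            synonyms: tuple[str, ...] = ()
            if len(fields) > 1 and fields[1].strip():
                synonyms = tuple(
                    normalize_gene_symbol(token)
                    for token in fields[1].split(",")
                    if token.strip()
                )
            entries.append((symbol, synonyms))
    return AnnotationTable(entries=tuple(entries))


def read_pathway_map(path: PathLike) -> Mapping[str, str]:
    """Read a two-column gene -> pathway-label TSV into a plain mapping."""
    frame = _read_tsv(path, ["gene", "pathway"])
    assignments: dict[str, str] = {}
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        gene = normalize_gene_symbol(str(row.gene))
        if gene in assignments:
            raise ValidationError(
                f"{path}: gene {gene!r} assigned twice (data row {row_number})"
            )
        assignments[gene] = str(row.pathway).strip()
    return assignments


_RESULT_COLUMNS = [
    "protein_id",
    "gene",
    "count_group1",
    "count_group2",
    "ratio",
    "log2fc",
    "p_value",
    "direction",
    "significant",
]


def _format_number(value: float) -> str:
    # at least 6 significant figures, and enough digits past the decimal
    # point that values of any magnitude survive a round trip within 1e-5
    if value == 0 or not math.isfinite(value):
        return f"{value:.{TSV_SIGFIGS}g}"
    magnitude = int(math.floor(math.log10(abs(value))))
    sigfigs = max(TSV_SIGFIGS, magnitude + TSV_SIGFIGS)
    return f"{value:.{sigfigs}g}"


def write_results_table(
    results: Sequence[DifferentialResult], path: PathLike
) -> None:
    """Write a per-protein differential-abundance report.

    Ratios and fold changes are printed at 6 significant figures; the table
    round-trips through :func:`read_results_table` to that precision.
    """
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(_RESULT_COLUMNS)
            for res in results:
                writer.writerow(
                    [
                        res.protein_id,
                        res.gene,
                        _format_number(res.c),
                        _format_number(res.s),
                        _format_number(res.ratio),
                        _format_number(res.log2fc),
                        "" if res.p_value is None else f"{res.p_value:.6g}",
                        res.direction.value,
                        str(res.significant).lower(),
                    ]
                )
    except OSError as exc:
        raise ConfigurationError(f"cannot write results table to {path}: {exc}") from exc


def read_results_table(path: PathLike) -> list[DifferentialResult]:
    """Read back a report written by :func:`write_results_table`."""
    frame = _read_tsv(path, _RESULT_COLUMNS)
    results: list[DifferentialResult] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        p_raw = row.p_value
        p_value = None if (p_raw is None or pd.isna(p_raw) or p_raw == "") else float(p_raw)
        results.append(
            DifferentialResult(
                protein_id=str(row.protein_id),
                gene=str(row.gene),
                c=float(row.count_group1),
                s=float(row.count_group2),
                ratio=float(row.ratio),
                log2fc=float(row.log2fc),
                p_value=p_value,
                direction=Direction(row.direction),
                significant=str(row.significant).lower() == "true",
            )
        )
    return results


def write_concordance_table(records, path: PathLike) -> None:
    """Write a per-gene, per-stage concordance report."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "gene",
                "stage",
                "tpm_ratio",
                "tpm_log2fc",
                "protein_direction",
                "transcript_direction",
                "concordant",
            ]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.gene,
                    rec.stage.value,
                    _format_number(rec.tpm_ratio),
                    _format_number(rec.tpm_log2fc),
                    rec.protein_direction.value,
                    rec.transcript_direction.value,
                    str(rec.concordant).lower(),
                ]
            )
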