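"""Domain records shared across the pipeline.

The quantification unit throughout is the *average unique-peptide count*: for
each protein the number of distinct peptide sequences identified per LC-MS
run, averaged over replicate runs of the same mitochondrial preparation.
Group 1 is cytotrophoblast mitochondria ("Cyto-Mito"), group 2
syncytiotrophoblast mitochondria ("Syncytio-Mito"); positive log2 fold
changes mean higher in the cytotrophoblast compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .errors import ValidationError

#: Default group labels, in (group 1, group 2) order.
DEFAULT_GROUPS: tuple[str, str] = ("cyto_mito", "syncytio_mito")

#: Default cell-type labels for expression tables, in the same order.
DEFAULT_CELL_TYPES: tuple[str, str] = ("cytotrophoblast", "syncytiotrophoblast")


class Stage(str, Enum):
    """Gestational stage of a single-cell expression table."""

    FIRST_TRIMESTER = "first_trimester"
    THIRD_TRIMESTER = "third_trimester"


class Direction(str, Enum):
    """Direction of a fold change relative to group 1 (cytotrophoblast)."""

    HIGHER_GROUP1 = "higher_group1"
    UNCHANGED = "unchanged"
    HIGHER_GROUP2 = "higher_group2"

    @property
    def sign(self) -> int:
        if self is Direction.HIGHER_GROUP1:
            return 1
        if self is Direction.HIGHER_GROUP2:
            return -1
        return 0


@dataclass(frozen=True)
class ProteinCounts:
    """One protein's averaged unique-peptide counts in each group.

    ``group_counts`` holds the mean over replicate runs; ``replicate_counts``,
    when available, holds the per-run integer counts it was averaged from.
    """

    protein_id: str
    gene: str
    group_counts: Mapping[str, float]
    replicate_counts: Optional[Mapping[str, Sequence[int]]] = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if len(self.group_counts) != 2:
            raise ValidationError(
                f"{self.protein_id}: expected exactly two group counts, "
                f"got {sorted(self.group_counts)}"
            )
        for group, value in self.group_counts.items():
            if value < 0:
                raise ValidationError(
                    f"{self.protein_id}: negative count {value!r} in group {group!r}"
                )
        if self.replicate_counts is not None:
            for group, runs in self.replicate_counts.items():
                if group not in self.group_counts:
                    raise ValidationError(
                        f"{self.protein_id}: replicate counts for unknown group {group!r}"
                    )
                if any(r < 0 for r in runs):
                    raise ValidationError(
                        f"{self.protein_id}: negative replicate count in group {group!r}"
                    )
                mean = sum(runs) / len(runs)
                # printed averages are rounded to integers, allow half a count
                if abs(mean - self.group_counts[group]) > 0.5:
                    raise ValidationError(
                        f"{self.protein_id}: group mean {self.group_counts[group]} "
                        f"inconsistent with replicates {list(runs)} (mean {mean:.3f})"
                    )


@dataclass(frozen=True)
class AnnotationTable:
    """A MitoCarta-style inventory: primary symbols with optional synonyms."""

    entries: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for symbol, _ in self.entries:
            if not symbol:
                raise ValidationError("annotation contains an empty symbol")
            if symbol in seen:
                raise ValidationError(f"duplicate annotation symbol {symbol!r}")
            seen.add(symbol)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's average TPM per trophoblast cell type at one stage."""

    gene: str
    stage: Stage
    tpm: Mapping[str, float]

    def __post_init__(self) -> None:
        if len(self.tpm) != 2:
            raise ValidationError(
                f"{self.gene}: expected exactly two cell-type TPM values, "
                f"got {sorted(self.tpm)}"
            )
        for cell_type, value in self.tpm.items():
            if value < 0:
                raise ValidationError(
                    f"{self.gene}: negative TPM {value!r} for {cell_type!r}"
                )


@dataclass(frozen=True)
class AnnotatedCounts:
    """A protein record with its mitochondrial-inventory match."""

    record: ProteinCounts
    is_mitochondrial: bool
    matched_symbol: Optional[str] = None

    def __post_init__(self) -> None:
        if self.is_mitochondrial != (self.matched_symbol is not None):
            raise ValidationError(
                f"{self.record.protein_id}: is_mitochondrial must mirror matched_symbol"
            )


@dataclass(frozen=True)
class DifferentialResult:
    """Ratio, log2 fold change, Fisher p and direction for one protein."""

    protein_id: str
    gene: str
    c: float
    s: float
    ratio: float
    log2fc: float
    p_value: Optional[float]
    direction: Direction
    significant: bool
    q_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.significant and self.p_value is None:
            raise ValidationError(f"{self.protein_id}: significant without a p-value")


@dataclass(frozen=True)
class ConcordanceRecord:
    """Direction agreement between protein and transcript for one gene/stage."""

    gene: str
    stage: Stage
    tpm_ratio: float
    tpm_log2fc: float
    protein_direction: Direction
    transcript_direction: Direction
    concordant: bool


@dataclass(frozen=True)
class ConcordanceSummary:
    per_stage_matches: Mapping[Stage, int]
    conserved_genes: frozenset[str]
    n_tested: Mapping[Stage, int]
    fraction_concordant: Mapping[Stage, float]


@dataclass(frozen=True)
class PathwayMap:
    """Gene symbol -> pathway label; every gene maps to exactly one label."""

    assignments: Mapping[str, str]

    def __len__(self) -> int:
        return len(self.assignments)
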