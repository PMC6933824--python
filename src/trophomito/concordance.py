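"""Proteome-transcriptome direction concordance.

For every gene present both in the differential proteomic results (isolated
mitochondria, term placenta) and in a single-cell TPM table (one per
gestational stage), the transcript fold change ``(TPM_cyt + kappa) /
(TPM_syn + kappa)`` is computed and its direction compared with the
proteomic direction.  A gene is *concordant* at a stage when both layers
move the same way and neither is unchanged; a gene is *conserved across
gestation* when it is concordant at every stage examined.

Only directions are compared, never magnitudes: spectral counts and TPM are
different units on different materials (isolated organelles vs whole
cells), so sign agreement is the strongest defensible cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .differential import classify_direction, log2_fold_change, pseudocount_ratio
from .types import (
    DEFAULT_CELL_TYPES,
    ConcordanceRecord,
    ConcordanceSummary,
    Direction,
    DifferentialResult,
    ExpressionRecord,
    Stage,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceConfig:
    """Stage-aware settings for the transcriptome comparison.

    The two published TPM tables follow different ratio conventions: the
    first-trimester table's printed ratios are plain ``TPM_cyt / TPM_syn``
    (kappa=0) while the third-trimester table's are pseudocounted with
    kappa=1 (which also keeps its zero-TPM genes finite).  Both knobs are
    per-stage configurable.
    """

    stage_pseudocounts: Mapping[Stage, float] = field(
        default_factory=lambda: {
            Stage.FIRST_TRIMESTER: 0.0,
            Stage.THIRD_TRIMESTER: 1.0,
        }
    )
    cell_types: tuple[str, str] = DEFAULT_CELL_TYPES
    unchanged_tolerance: float = 0.0

    def pseudocount_for(self, stage: Stage) -> float:
        return self.stage_pseudocounts.get(stage, 1.0)


def expression_fold_change(
    record: ExpressionRecord,
    pseudocount: float,
    cell_types: tuple[str, str] = DEFAULT_CELL_TYPES,
) -> tuple[float, float]:
    """(ratio, log2fc) of one gene's TPM pair, cytotrophoblast over
    syncytiotrophoblast, through the shared pseudocount-ratio path."""
    cyt, syn = cell_types
    ratio = pseudocount_ratio(record.tpm[cyt], record.tpm[syn], pseudocount)
    return ratio, log2_fold_change(ratio)


def match_directions(
    proteomic: Sequence[DifferentialResult],
    expression: Sequence[ExpressionRecord],
    config: Optional[ConcordanceConfig] = None,
) -> list[ConcordanceRecord]:
    """Pair proteomic directions with transcript directions per (gene, stage).

    Genes present on only one side are skipped (logged at debug level).
    A pair is concordant iff both directions agree and neither is
    "unchanged".
    """
    config = config or ConcordanceConfig()
    protein_direction = {res.gene: res.direction for res in proteomic}

    records: list[ConcordanceRecord] = []
    skipped: list[str] = []
    for exp in expression:
        direction = protein_direction.get(exp.gene)
        if direction is None:
            skipped.append(exp.gene)
            continue
        kappa = config.pseudocount_for(exp.stage)
        ratio, log2fc = expression_fold_change(exp, kappa, config.cell_types)
        transcript_direction = classify_direction(ratio, config.unchanged_tolerance)
        concordant = (
            direction is transcript_direction
            and direction is not Direction.UNCHANGED
        )
        records.append(
            ConcordanceRecord(
                gene=exp.gene,
                stage=exp.stage,
                tpm_ratio=ratio,
                tpm_log2fc=log2fc,
                protein_direction=direction,
                transcript_direction=transcript_direction,
                concordant=concordant,
            )
        )
    if skipped:
        logger.info(
            "%d expression genes had no proteomic counterpart and were "
            "skipped: %s",
            len(skipped),
            ", ".join(sorted(skipped)),
        )
    return records


def summarize_concordance(
    records: Sequence[ConcordanceRecord],
) -> ConcordanceSummary:
    """Per-stage concordant counts plus the conserved-across-gestation set.

    ``conserved_genes`` is the intersection over all stages present in the
    input of each stage's concordant gene set; with a single stage it
    degenerates to that stage's concordant genes.
    """
    stages = sorted({rec.stage for rec in records}, key=lambda s: s.value)
    per_stage_matches: dict[Stage, int] = {}
    n_tested: dict[Stage, int] = {}
    fraction: dict[Stage, float] = {}
    concordant_sets: list[set[str]] = []
    for stage in stages:
        stage_records = [rec for rec in records if rec.stage is stage]
        matches = {rec.gene for rec in stage_records if rec.concordant}
        per_stage_matches[stage] = len(matches)
        n_tested[stage] = len(stage_records)
        fraction[stage] = len(matches) / len(stage_records) if stage_records else 0.0
        concordant_sets.append(matches)
    conserved = (
        frozenset(set.intersection(*concordant_sets)) if concordant_sets else frozenset()
    )
    return ConcordanceSummary(
        per_stage_matches=per_stage_matches,
        conserved_genes=conserved,
        n_tested=n_tested,
        fraction_concordant=fraction,
    )
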