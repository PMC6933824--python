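"""YAML configuration for pipeline runs.

A config file is a flat mapping; every key is optional and falls back to
the package defaults (which reproduce the packaged term-placenta analysis).
Command-line flags override file values.

Example::

    groups: [cyto_mito, syncytio_mito]
    pseudocount: 1
    alpha: 0.05
    min_unique_peptides: 3
    background_mode: column_totals
    stage_pseudocounts:
      first_trimester: 0
      third_trimester: 1
    count_columns:
      protein_id: "Protein ID"
      gene: "Gene name"
      groups:
        cyto_mito: "Average unique peptides Cyto-Mito"
        syncytio_mito: "Average unique peptides Syncytio-Mito"
    expression_columns:
      gene: Gene
      tpm:
        cytotrophoblast: CYT
        syncytiotrophoblast: SYN
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .concordance import ConcordanceConfig
from .differential import TestConfig
from .errors import ConfigurationError
from .tabular_io import CountTableFormat, ExpressionTableFormat
from .types import DEFAULT_GROUPS, Stage


@dataclass(frozen=True)
class PipelineConfig:
    test: TestConfig = field(default_factory=TestConfig)
    concordance: ConcordanceConfig = field(default_factory=ConcordanceConfig)
    count_format: CountTableFormat = field(default_factory=CountTableFormat)
    expression_format: ExpressionTableFormat = field(
        default_factory=ExpressionTableFormat
    )
    pathway_map_path: Optional[Path] = None


def _as_mapping(value: Any, key: str) -> Mapping[str, Any]:
    if not isinstance(value, Mapping):
        raise ConfigurationError(f"config key {key!r} must be a mapping")
    return value


def load_config(
    path: Optional[Union[str, Path]] = None, **overrides: Any
) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file.

    ``overrides`` (typically CLI flags) take precedence over file values;
    ``None`` overrides are ignored.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        raw.update(loaded)
    for key, value in overrides.items():
        if value is not None:
            raw[key] = value

    groups = tuple(raw.get("groups", DEFAULT_GROUPS))
    if len(groups) != 2:
        raise ConfigurationError(f"groups must list exactly two labels, got {groups}")

    explicit_totals = raw.get("explicit_totals")
    if explicit_totals is not None:
        explicit_totals = tuple(int(v) for v in explicit_totals)

    test = TestConfig(
        pseudocount=float(raw.get("pseudocount", 1.0)),
        alpha=float(raw.get("alpha", 0.05)),
        min_unique_peptides=float(raw.get("min_unique_peptides", 3.0)),
        unchanged_tolerance=float(raw.get("unchanged_tolerance", 0.0)),
        background_mode=str(raw.get("background_mode", "column_totals")),
        explicit_totals=explicit_totals,
        group_labels=groups,  # type: ignore[arg-type]
        compute_q_values=bool(raw.get("compute_q_values", False)),
    )

    stage_pseudocounts = {
        Stage.FIRST_TRIMESTER: 0.0,
        Stage.THIRD_TRIMESTER: 1.0,
    }
    for stage_name, value in _as_mapping(
        raw.get("stage_pseudocounts", {}), "stage_pseudocounts"
    ).items():
        stage_pseudocounts[Stage(stage_name)] = float(value)
    concordance = ConcordanceConfig(
        stage_pseudocounts=stage_pseudocounts,
        unchanged_tolerance=float(
            raw.get("concordance_unchanged_tolerance", test.unchanged_tolerance)
        ),
    )

    count_format = CountTableFormat(group_labels=groups, group_columns={g: g for g in groups})
    if "count_columns" in raw:
        cols = _as_mapping(raw["count_columns"], "count_columns")
        replicate_columns = cols.get("replicates")
        count_format = CountTableFormat(
            protein_id_column=str(cols.get("protein_id", "protein_id")),
            gene_column=str(cols.get("gene", "gene")),
            group_columns=cols.get("groups"),
            replicate_columns=replicate_columns,
            group_labels=groups,  # type: ignore[arg-type]
        )

    expression_format = ExpressionTableFormat()
    if "expression_columns" in raw:
        cols = _as_mapping(raw["expression_columns"], "expression_columns")
        expression_format = ExpressionTableFormat(
            gene_column=str(cols.get("gene", "gene")),
            tpm_columns=dict(_as_mapping(cols.get("tpm", {}), "expression_columns.tpm")),
        )

    pathway_map_path = raw.get("pathway_map")
    return PipelineConfig(
        test=test,
        concordance=concordance,
        count_format=count_format,
        expression_format=expression_format,
        pathway_map_path=Path(pathway_map_path) if pathway_map_path else None,
    )
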