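"""End-to-end orchestration: annotate -> filter -> test -> summarize -> concordance.

One call produces the differential TSV, the concordance TSV, a
machine-readable JSON summary, and a run manifest recording input digests,
the config snapshot, package version and seed.  Outputs are byte-identical
across reruns with identical inputs and config (the manifest's timestamp
field aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from . import __version__
from .annotation import annotate_mitochondrial
from .concordance import match_directions, summarize_concordance
from .config import PipelineConfig
from .differential import (
    assign_pathways,
    run_differential,
    summarize_directions,
)
from .errors import TrophomitoError
from .tabular_io import (
    read_annotation_table,
    read_expression_table,
    read_pathway_map,
    read_peptide_counts,
    write_concordance_table,
    write_results_table,
)
from .types import ConcordanceSummary, DifferentialResult, Stage

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


@dataclass(frozen=True)
class PipelineArtifacts:
    differential_table: Path
    concordance_table: Optional[Path]
    summary_json: Path
    manifest_json: Path
    summary: dict
    results: tuple[DifferentialResult, ...]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with path.open("rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _config_snapshot(config: PipelineConfig) -> dict:
    def encode(value):
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            return {
                f.name: encode(getattr(value, f.name))
                for f in dataclasses.fields(value)
            }
        if isinstance(value, Mapping):
            return {str(getattr(k, "value", k)): encode(v) for k, v in value.items()}
        if isinstance(value, Path):
            return str(value)
        if isinstance(value, (list, tuple)):
            return [encode(v) for v in value]
        return value

    return encode(config)


def _concordance_summary_dict(summary: ConcordanceSummary) -> dict:
    return {
        "per_stage_matches": {
            stage.value: count for stage, count in summary.per_stage_matches.items()
        },
        "n_tested": {stage.value: n for stage, n in summary.n_tested.items()},
        "fraction_concordant": {
            stage.value: fraction
            for stage, fraction in summary.fraction_concordant.items()
        },
        "conserved_genes": sorted(summary.conserved_genes),
        "n_conserved": len(summary.conserved_genes),
    }


def run_pipeline(
    count_path: PathLike,
    annotation_path: PathLike,
    expression_paths: Optional[Mapping[Stage, PathLike]] = None,
    config: Optional[PipelineConfig] = None,
    out_dir: PathLike = "results",
    seed: Optional[int] = None,
) -> PipelineArtifacts:
    """Run the full analysis and write all artifacts under ``out_dir``.

    The manifest is written even when a stage fails, with the error recorded.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expression_paths = dict(expression_paths or {})

    inputs: dict[str, str] = {}
    for path in [count_path, annotation_path, *expression_paths.values()]:
        path = Path(path)
        if path.exists():
            inputs[str(path)] = _sha256(path)
        else:
            inputs[str(path)] = "MISSING"

    manifest: dict = {
        "package": "trophomito",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": _config_snapshot(config),
        "inputs": inputs,
        "outputs": {},
        "status": "started",
    }
    manifest_path = out_dir / "manifest.json"

    def flush_manifest() -> None:
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )

    try:
        counts = read_peptide_counts(count_path, config.count_format)
        annotation = read_annotation_table(annotation_path)
        annotated = annotate_mitochondrial(counts, annotation)
        results = run_differential(annotated, config.test)

        differential_path = out_dir / "differential.tsv"
        write_results_table(results, differential_path)
        manifest["outputs"]["differential"] = str(differential_path)

        n_up, n_unchanged, n_down = summarize_directions(results)
        summary: dict = {
            "n_input_proteins": len(counts),
            "n_mitochondrial": sum(1 for rec in annotated if rec.is_mitochondrial),
            "n_tested": len(results),
            "n_significant": sum(1 for res in results if res.significant),
            "directions": {
                "higher_group1": n_up,
                "unchanged": n_unchanged,
                "higher_group2": n_down,
            },
        }

        pathway_map = None
        if config.pathway_map_path is not None:
            pathway_map = read_pathway_map(config.pathway_map_path)
        else:
            from .datasets import load_pathway_map

            pathway_map = load_pathway_map("blocks")
        significant = [res for res in results if res.significant]
        summary["pathway_counts"] = assign_pathways(significant, pathway_map)

        concordance_path: Optional[Path] = None
        if expression_paths:
            expression = []
            for stage, path in sorted(
                expression_paths.items(), key=lambda item: item[0].value
            ):
                expression.extend(
                    read_expression_table(path, stage, config.expression_format)
                )
            records = match_directions(results, expression, config.concordance)
            concordance_path = out_dir / "concordance.tsv"
            write_concordance_table(records, concordance_path)
            manifest["outputs"]["concordance"] = str(concordance_path)
            conc_summary = summarize_concordance(records)
            summary["concordance"] = _concordance_summary_dict(conc_summary)
            summary["concordance"]["n_distinct_concordant"] = len(
                {rec.gene for rec in records if rec.concordant}
            )

        summary_path = out_dir / "summary.json"
        summary_path.write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest["outputs"]["summary"] = str(summary_path)
        manifest["status"] = "ok"
        flush_manifest()
        return PipelineArtifacts(
            differential_table=differential_path,
            concordance_table=concordance_path,
            summary_json=summary_path,
            manifest_json=manifest_path,
            summary=summary,
            results=tuple(results),
        )
    except TrophomitoError as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        flush_manifest()
        raise
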