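"""Synthetic spectral-count experiments with known ground truth.

The generator emulates the structure of the real experiment: per-protein
baseline abundances drawn log-normal (spectral counts span orders of
magnitude), triplicate runs per group with Poisson count noise, a fraction
of proteins carrying a planted fold change between the two mitochondrial
populations, and paired per-stage TPM tables whose direction agrees with
the planted protein effect with a controllable probability.

Planted fold changes are applied to the group-2 (syncytiotrophoblast) rate
before a single depth scaling derived from the baseline rates, so the
realized expected count ratio of a planted protein equals its nominal fold
change; group expected run totals equal the configured depth exactly for
group 1 and up to the (small) compositional shift the planted effects
induce for group 2.

It makes no attempt at peptide-sequence realism, identification error, or
the between-run correlation of real LC-MS data; see the methods note for
what that implies about test conclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import annotate_mitochondrial  # noqa: F401  (re-exported convenience)
from .differential import TestConfig, run_differential
from .errors import ValidationError
from .types import (
    DEFAULT_GROUPS,
    AnnotatedCounts,
    Direction,
    ExpressionRecord,
    ProteinCounts,
    Stage,
)


@dataclass(frozen=True)
class FoldChangeSpec:
    """Distribution of planted fold-change magnitudes (all > 1).

    Either a single fixed value or a log-uniform range.  The *direction*
    of each planted effect is drawn separately (``de_up_fraction``).
    """

    fixed: Optional[float] = 2.0
    log_uniform: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if (self.fixed is None) == (self.log_uniform is None):
            raise ValidationError(
                "specify exactly one of fixed or log_uniform fold change"
            )
        if self.fixed is not None and self.fixed <= 1:
            raise ValidationError("fixed fold change must exceed 1")
        if self.log_uniform is not None:
            lo, hi = self.log_uniform
            if not 1 < lo <= hi:
                raise ValidationError("log-uniform bounds must satisfy 1 < lo <= hi")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.fixed is not None:
            return np.full(size, float(self.fixed))
        lo, hi = self.log_uniform  # type: ignore[misc]
        return np.exp(rng.uniform(math.log(lo), math.log(hi), size))


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic experiment.

    Defaults emulate the real study: triplicate runs, ~5000 unique-peptide
    identifications per group per run (the scale of the published column
    totals), log-normal abundance spread covering counts from ~0 to a few
    hundred, a modest differential fraction with a 64:36 up:down split, and
    87.5% proteome-transcriptome direction agreement for planted effects.
    """

    n_proteins: int = 500
    n_replicates: int = 3
    abundance_log_mean: float = 2.3
    abundance_log_sd: float = 1.0
    depth: Mapping[str, float] = field(
        default_factory=lambda: {DEFAULT_GROUPS[0]: 5000.0, DEFAULT_GROUPS[1]: 5000.0}
    )
    de_fraction: float = 0.1
    fold_changes: FoldChangeSpec = field(default_factory=FoldChangeSpec)
    de_up_fraction: float = 0.64
    concordance_prob: float = 0.875
    overdispersion: float = 0.0
    seed: int = 0
    group_labels: tuple[str, str] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be at least 1")
        for prob_name in ("de_fraction", "de_up_fraction", "concordance_prob"):
            value = getattr(self, prob_name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{prob_name} must lie in [0, 1], got {value}")
        if set(self.depth) != set(self.group_labels):
            raise ValidationError(
                f"depth keys {sorted(self.depth)} must equal group labels "
                f"{sorted(self.group_labels)}"
            )
        if any(d <= 0 for d in self.depth.values()):
            raise ValidationError("depths must be positive")
        if self.overdispersion < 0:
            raise ValidationError("overdispersion must be non-negative")
        if self.abundance_log_sd < 0:
            raise ValidationError("abundance_log_sd must be non-negative")


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated experiment.

    ``fold_change`` is the group-1 over group-2 rate ratio (1.0 for
    non-differential proteins).  ``transcript_direction`` is filled in by
    :func:`simulate_expression_tables`.
    """

    protein_ids: tuple[str, ...]
    genes: tuple[str, ...]
    fold_change: np.ndarray
    is_de: np.ndarray
    transcript_direction: dict[tuple[str, Stage], Direction] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if np.any(self.fold_change[~self.is_de] != 1.0):
            raise ValidationError("non-differential proteins must have fold change 1")

    def protein_sign(self, gene: str) -> int:
        index = self.genes.index(gene)
        fold = self.fold_change[index]
        return 0 if fold == 1.0 else (1 if fold > 1.0 else -1)


def _sample_counts(
    rng: np.random.Generator,
    rates: np.ndarray,
    n_replicates: int,
    overdispersion: float,
) -> np.ndarray:
    """(n_proteins, n_replicates) counts; gamma-Poisson when overdispersed."""
    shape = (rates.size, n_replicates)
    lam = np.broadcast_to(rates[:, None], shape)
    if overdispersion > 0:
        # gamma-Poisson with Var = mu + overdispersion * mu^2
        gamma_shape = 1.0 / overdispersion
        lam = rng.gamma(gamma_shape, lam * overdispersion, size=shape)
    return rng.poisson(lam)


def simulate_peptide_counts(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[ProteinCounts], SimulatedTruth]:
    """Draw one synthetic experiment; reproducible from ``config.seed``."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_proteins
    g1, g2 = config.group_labels

    baseline = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd, n)
    is_de = rng.random(n) < config.de_fraction
    magnitudes = config.fold_changes.draw(rng, n)
    up = rng.random(n) < config.de_up_fraction
    fold = np.where(is_de, np.where(up, magnitudes, 1.0 / magnitudes), 1.0)

    scale = {label: config.depth[label] / baseline.sum() for label in (g1, g2)}
    rate_g1 = baseline * scale[g1]
    rate_g2 = (baseline / fold) * scale[g2]

    counts_g1 = _sample_counts(rng, rate_g1, config.n_replicates, config.overdispersion)
    counts_g2 = _sample_counts(rng, rate_g2, config.n_replicates, config.overdispersion)

    width = max(5, len(str(n)))
    protein_ids = tuple(f"SIMP{i:0{width}d}" for i in range(n))
    genes = tuple(f"SIMG{i:0{width}d}" for i in range(n))
    records = [
        ProteinCounts(
            protein_id=protein_ids[i],
            gene=genes[i],
            group_counts={
                g1: counts_g1[i].mean(),
                g2: counts_g2[i].mean(),
            },
            replicate_counts={
                g1: tuple(int(x) for x in counts_g1[i]),
                g2: tuple(int(x) for x in counts_g2[i]),
            },
        )
        for i in range(n)
    ]
    truth = SimulatedTruth(
        protein_ids=protein_ids,
        genes=genes,
        fold_change=fold,
        is_de=is_de,
    )
    return records, truth


def simulate_expression_tables(
    truth: SimulatedTruth,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    stages: Sequence[Stage] = (Stage.FIRST_TRIMESTER, Stage.THIRD_TRIMESTER),
) -> dict[Stage, list[ExpressionRecord]]:
    """Paired TPM tables whose directions track the protein truth.

    For each planted-effect gene and stage, the transcript moves in the
    protein's direction with probability ``concordance_prob`` and opposite
    otherwise; genes without a planted effect move either way with equal
    probability.  Magnitudes are log-normal and independent of the protein
    effect size.  The drawn transcript directions are recorded in
    ``truth.transcript_direction``.
    """
    rng = rng if rng is not None else np.random.default_rng([config.seed, 1])
    cyt, syn = ("cytotrophoblast", "syncytiotrophoblast")
    tables: dict[Stage, list[ExpressionRecord]] = {}
    for stage in stages:
        records: list[ExpressionRecord] = []
        for index, gene in enumerate(truth.genes):
            base = rng.lognormal(config.abundance_log_mean, config.abundance_log_sd)
            half_log2 = abs(rng.normal(1.0, 0.5)) / 2 + 0.05  # effect never exactly 0
            protein_fold = truth.fold_change[index]
            if protein_fold == 1.0:
                sign = 1 if rng.random() < 0.5 else -1
            else:
                sign = 1 if protein_fold > 1.0 else -1
                if rng.random() >= config.concordance_prob:
                    sign = -sign
            tpm_cyt = base * 2.0 ** (sign * half_log2)
            tpm_syn = base * 2.0 ** (-sign * half_log2)
            truth.transcript_direction[(gene, stage)] = (
                Direction.HIGHER_GROUP1 if sign > 0 else Direction.HIGHER_GROUP2
            )
            records.append(
                ExpressionRecord(gene=gene, stage=stage, tpm={cyt: tpm_cyt, syn: tpm_syn})
            )
        tables[stage] = records
    return tables


def as_annotated(records: Sequence[ProteinCounts]) -> list[AnnotatedCounts]:
    """Wrap simulated records as mitochondrial-flagged inputs for the
    differential stage (the simulation universe is all-mitochondrial)."""
    return [
        AnnotatedCounts(record=rec, is_mitochondrial=True, matched_symbol=rec.gene)
        for rec in records
    ]


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Aggregate error rates of the differential procedure on simulations."""

    type_i_error: float
    type_i_se: float
    n_null_tests: int
    power: float
    power_se: float
    n_de_tests: int
    sign_error_rate: float
    sign_error_se: float
    n_significant_de: int
    n_sims: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["type_I_error", "power", "sign_error_rate"],
                "value": [self.type_i_error, self.power, self.sign_error_rate],
                "se": [self.type_i_se, self.power_se, self.sign_error_se],
                "n": [self.n_null_tests, self.n_de_tests, self.n_significant_de],
            }
        )


def _binomial_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n > 0 else float("nan")


def evaluate_operating_characteristics(
    config: SimulationConfig,
    test_config: Optional[TestConfig] = None,
    n_sims: int = 100,
) -> OperatingCharacteristics:
    """Run the full differential stage on ``n_sims`` independent experiments.

    type I error: significant fraction among proteins without a planted
    effect; power: significant-with-correct-sign fraction among planted
    proteins; sign error rate: wrong-direction fraction among significant
    calls on planted proteins.  Each simulation uses an independent random
    stream keyed by ``(config.seed, simulation index)``.
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be at least 1")
    test_config = test_config or TestConfig(group_labels=config.group_labels)

    n_null = n_fp = 0
    n_de = n_power = 0
    n_sig_de = n_sign_err = 0
    for sim_index in range(n_sims):
        rng = np.random.default_rng([config.seed, sim_index])
        records, truth = simulate_peptide_counts(config, rng=rng)
        results = run_differential(as_annotated(records), test_config)
        truth_index = {pid: i for i, pid in enumerate(truth.protein_ids)}
        for res in results:
            i = truth_index[res.protein_id]
            if truth.is_de[i]:
                n_de += 1
                true_sign = 1 if truth.fold_change[i] > 1 else -1
                if res.significant:
                    n_sig_de += 1
                    if res.direction.sign == true_sign:
                        n_power += 1
                    elif res.direction.sign == -true_sign:
                        n_sign_err += 1
            else:
                n_null += 1
                if res.significant:
                    n_fp += 1

    type_i = n_fp / n_null if n_null else float("nan")
    power = n_power / n_de if n_de else float("nan")
    sign_err = n_sign_err / n_sig_de if n_sig_de else 0.0
    return OperatingCharacteristics(
        type_i_error=type_i,
        type_i_se=_binomial_se(type_i, n_null),
        n_null_tests=n_null,
        power=power,
        power_se=_binomial_se(power, n_de),
        n_de_tests=n_de,
        sign_error_rate=sign_err,
        sign_error_se=_binomial_se(sign_err, n_sig_de),
        n_significant_de=n_sig_de,
        n_sims=n_sims,
    )
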