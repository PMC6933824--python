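"""Differential abundance of spectral counts between mitochondrial populations.

The quantification model is deliberately simple, mirroring label-free
spectral counting practice:

* abundance ratio for a protein with averaged unique-peptide counts
  ``c`` (cytotrophoblast mitochondria) and ``s`` (syncytiotrophoblast
  mitochondria) is ``R = (c + kappa) / (s + kappa)`` with pseudocount
  ``kappa`` (default 1), which keeps zero-count proteins finite;
* fold change is ``log2(R)``;
* significance comes from a two-sided Fisher's exact test of the protein's
  counts against the background totals of all retained proteins, on the 2x2
  table ``[[c, s], [C_tot - c, S_tot - s]]``.

The Fisher p-value is computed by exact integer enumeration of the
hypergeometric distribution (minimum-likelihood two-sided definition: sum
the probabilities of all tables whose point probability does not exceed the
observed one).  Integer arithmetic makes tie handling exact, which floating
point implementations cannot guarantee.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Optional, Sequence, Union

from .errors import ValidationError
from .types import (
    DEFAULT_GROUPS,
    AnnotatedCounts,
    Direction,
    DifferentialResult,
    PathwayMap,
)

logger = logging.getLogger(__name__)

UNASSIGNED_PATHWAY = "unassigned"


@dataclass(frozen=True)
class TestConfig:
    """Parameters of the differential-abundance procedure.

    pseudocount
        kappa added to numerator and denominator of the ratio (default 1).
    alpha
        raw-p significance level (default 0.05, no multiplicity correction
        by default — optional Benjamini-Hochberg q-values can be attached).
    min_unique_peptides
        identification filter: a protein is retained when its *maximum*
        group count reaches this value (default 3).  The maximum — not both
        groups — must pass, so a protein absent from one population but
        well-identified in the other is kept.
    unchanged_tolerance
        half-width of the "unchanged" ratio band; 0 means only an exact
        ratio of 1 counts as unchanged.
    background_mode
        "column_totals" derives the Fisher background from the column sums
        of the retained proteins' rounded counts; "explicit" uses
        ``explicit_totals``.
    """

    __test__ = False  # prevent pytest from collecting this config class

    pseudocount: float = 1.0
    alpha: float = 0.05
    min_unique_peptides: float = 3.0
    unchanged_tolerance: float = 0.0
    background_mode: str = "column_totals"
    explicit_totals: Optional[tuple[int, int]] = None
    group_labels: tuple[str, str] = DEFAULT_GROUPS
    compute_q_values: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")
        if self.min_unique_peptides < 0:
            raise ValidationError("min_unique_peptides must be non-negative")
        if self.unchanged_tolerance < 0:
            raise ValidationError("unchanged_tolerance must be non-negative")
        if self.background_mode not in ("column_totals", "explicit"):
            raise ValidationError(
                f"unknown background_mode {self.background_mode!r}"
            )
        if self.background_mode == "explicit":
            if self.explicit_totals is None:
                raise ValidationError(
                    "background_mode='explicit' requires explicit_totals"
                )
            if any(total <= 0 for total in self.explicit_totals):
                raise ValidationError("explicit totals must be positive")


def pseudocount_ratio(c: float, s: float, pseudocount: float = 1.0) -> float:
    """Abundance ratio ``(c + kappa) / (s + kappa)``.

    With the default kappa=1 a 7-vs-0 protein maps to ratio 8 rather than
    infinity.  kappa=0 recovers the plain ratio and is undefined at s=0.
    """
    if c < 0 or s < 0:
        raise ValidationError(f"counts must be non-negative, got ({c}, {s})")
    if pseudocount < 0:
        raise ValidationError(f"pseudocount must be non-negative, got {pseudocount}")
    denominator = s + pseudocount
    if denominator == 0:
        raise ValidationError(
            "ratio undefined: denominator count and pseudocount are both zero"
        )
    if c + pseudocount == 0:
        raise ValidationError(
            "ratio degenerate: numerator count and pseudocount are both zero"
        )
    return (c + pseudocount) / denominator


def log2_fold_change(ratio: float) -> float:
    """log base 2 of a positive abundance ratio."""
    if ratio <= 0:
        raise ValidationError(f"ratio must be positive, got {ratio}")
    return math.log2(ratio)


def classify_direction(ratio: float, tolerance: float = 0.0) -> Direction:
    """Classify a ratio as higher in group 1, unchanged, or higher in group 2.

    The unchanged band is multiplicative and symmetric:
    ``1/(1+tolerance) <= ratio <= 1+tolerance``.
    """
    if ratio <= 0:
        raise ValidationError(f"ratio must be positive, got {ratio}")
    if tolerance < 0:
        raise ValidationError(f"tolerance must be non-negative, got {tolerance}")
    if ratio > 1.0 + tolerance:
        return Direction.HIGHER_GROUP1
    if ratio < 1.0 / (1.0 + tolerance):
        return Direction.HIGHER_GROUP2
    return Direction.UNCHANGED


def _validate_fisher_inputs(c: int, s: int, C_tot: int, S_tot: int) -> None:
    for name, value in (("c", c), ("s", s), ("C_tot", C_tot), ("S_tot", S_tot)):
        if value != int(value):
            raise ValidationError(f"{name} must be an integer, got {value!r}")
    if C_tot <= 0 or S_tot <= 0:
        raise ValidationError("background totals must be positive")
    if c < 0 or s < 0:
        raise ValidationError("counts must be non-negative")
    if c > C_tot or s > S_tot:
        raise ValidationError(
            f"counts ({c}, {s}) exceed background totals ({C_tot}, {S_tot})"
        )


def fisher_background_test(c: int, s: int, C_tot: int, S_tot: int) -> float:
    """Two-sided Fisher's exact p for one protein against the background.

    Table: ``[[c, s], [C_tot - c, S_tot - s]]``.  Conditioning on the
    margins, the first cell is hypergeometric; the two-sided p sums the
    point probabilities of every table at most as likely as the observed
    one.  All weights are exact integers, so ties are resolved exactly.
    """
    _validate_fisher_inputs(c, s, C_tot, S_tot)
    c, s, C_tot, S_tot = int(c), int(s), int(C_tot), int(S_tot)
    n = c + s
    lo = max(0, n - S_tot)
    hi = min(n, C_tot)
    observed = math.comb(C_tot, c) * math.comb(S_tot, s)
    numerator = 0
    for k in range(lo, hi + 1):
        weight = math.comb(C_tot, k) * math.comb(S_tot, n - k)
        if weight <= observed:
            numerator += weight
    p = Fraction(numerator, math.comb(C_tot + S_tot, n))
    return min(1.0, float(p))


def fisher_background_pvalues(
    row_total: int, C_tot: int, S_tot: int
) -> dict[int, float]:
    """Two-sided Fisher p for every feasible first cell at fixed margins.

    Returns ``{c: p}`` for all ``c`` compatible with row total
    ``n = c + s`` and column totals ``(C_tot, S_tot)``.  Equivalent to
    calling :func:`fisher_background_test` for each table but computed in
    one pass (sorted exact weights + prefix sums), which makes exhaustive
    sweeps over margin space cheap.
    """
    if C_tot <= 0 or S_tot <= 0:
        raise ValidationError("background totals must be positive")
    if not 0 <= row_total <= C_tot + S_tot:
        raise ValidationError("row total outside feasible range")
    lo = max(0, row_total - S_tot)
    hi = min(row_total, C_tot)
    ks = range(lo, hi + 1)
    # exact multiplicative recurrence over the support: one big-int multiply
    # and one exact division per step instead of two binomials per k
    n = row_total
    weights = [math.comb(C_tot, lo) * math.comb(S_tot, n - lo)]
    for k in range(lo, hi):
        weights.append(
            weights[-1] * (C_tot - k) * (n - k) // ((k + 1) * (S_tot - n + k + 1))
        )
    order = sorted(weights)
    prefix = [0]
    for w in order:
        prefix.append(prefix[-1] + w)
    denom = math.comb(C_tot + S_tot, row_total)
    out: dict[int, float] = {}
    for k, w in zip(ks, weights):
        numerator = prefix[bisect_right(order, w)]
        out[k] = min(1.0, float(Fraction(numerator, denom)))
    return out


def round_half_up(value: float) -> int:
    """Round a non-negative average to the nearest integer, halves up."""
    if value < 0:
        raise ValidationError(f"cannot round negative count {value}")
    return int(math.floor(value + 0.5))


def run_differential(
    records: Sequence[AnnotatedCounts], config: Optional[TestConfig] = None
) -> list[DifferentialResult]:
    """Full differential stage on annotated count records.

    1. restrict to mitochondrial-flagged records;
    2. drop proteins whose maximum group count is below the
       identification filter;
    3. build background totals (column sums of the retained proteins'
       rounded counts, or the configured explicit totals);
    4. per protein: pseudocount ratio, log2 fold change, direction,
       Fisher p against the background, significance at alpha.

    Output order equals input order.  Ratios use the raw averaged counts;
    only the Fisher test sees rounded integers.
    """
    config = config or TestConfig()
    g1, g2 = config.group_labels

    mito = [rec for rec in records if rec.is_mitochondrial]
    if records and not mito:
        logger.warning(
            "none of the %d input proteins matched the mitochondrial inventory",
            len(records),
        )
    retained = [
        rec
        for rec in mito
        if max(rec.record.group_counts[g1], rec.record.group_counts[g2])
        >= config.min_unique_peptides
    ]
    dropped = len(mito) - len(retained)
    if dropped:
        logger.info(
            "identification filter (>=%g unique peptides in the better group) "
            "dropped %d of %d mitochondrial proteins",
            config.min_unique_peptides,
            dropped,
            len(mito),
        )
    if not retained:
        logger.warning("no proteins retained; returning empty result list")
        return []

    rounded = [
        (round_half_up(rec.record.group_counts[g1]), round_half_up(rec.record.group_counts[g2]))
        for rec in retained
    ]
    if config.background_mode == "explicit":
        assert config.explicit_totals is not None
        C_tot, S_tot = config.explicit_totals
        for (c_int, s_int), rec in zip(rounded, retained):
            if c_int > C_tot or s_int > S_tot:
                raise ValidationError(
                    f"{rec.record.protein_id}: counts ({c_int}, {s_int}) exceed "
                    f"explicit background totals ({C_tot}, {S_tot})"
                )
    else:
        C_tot = sum(c_int for c_int, _ in rounded)
        S_tot = sum(s_int for _, s_int in rounded)
    degenerate_background = C_tot == 0 or S_tot == 0
    if degenerate_background:
        logger.warning(
            "background column total is zero (C_tot=%d, S_tot=%d); "
            "Fisher p-values are undefined and reported as absent",
            C_tot,
            S_tot,
        )

    results: list[DifferentialResult] = []
    pvalue_cache: dict[int, dict[int, float]] = {}
    for (c_int, s_int), rec in zip(rounded, retained):
        c = rec.record.group_counts[g1]
        s = rec.record.group_counts[g2]
        ratio = pseudocount_ratio(c, s, config.pseudocount)
        log2fc = log2_fold_change(ratio)
        direction = classify_direction(ratio, config.unchanged_tolerance)
        if degenerate_background:
            p_value = None
        else:
            row_total = c_int + s_int
            if row_total not in pvalue_cache:
                pvalue_cache[row_total] = fisher_background_pvalues(
                    row_total, C_tot, S_tot
                )
            p_value = pvalue_cache[row_total][c_int]
        results.append(
            DifferentialResult(
                protein_id=rec.record.protein_id,
                gene=rec.matched_symbol or rec.record.gene,
                c=c,
                s=s,
                ratio=ratio,
                log2fc=log2fc,
                p_value=p_value,
                direction=direction,
                significant=p_value is not None and p_value <= config.alpha,
            )
        )

    if config.compute_q_values and results and not degenerate_background:
        from statsmodels.stats.multitest import multipletests

        _, q_values, _, _ = multipletests(
            [res.p_value for res in results], method="fdr_bh"
        )
        results = [
            DifferentialResult(
                protein_id=res.protein_id,
                gene=res.gene,
                c=res.c,
                s=res.s,
                ratio=res.ratio,
                log2fc=res.log2fc,
                p_value=res.p_value,
                direction=res.direction,
                significant=res.significant,
                q_value=float(q),
            )
            for res, q in zip(results, q_values)
        ]
    return results


def summarize_directions(
    results: Sequence[DifferentialResult],
) -> tuple[int, int, int]:
    """Count results per direction: (higher_group1, unchanged, higher_group2)."""
    n_up = sum(1 for r in results if r.direction is Direction.HIGHER_GROUP1)
    n_unchanged = sum(1 for r in results if r.direction is Direction.UNCHANGED)
    n_down = sum(1 for r in results if r.direction is Direction.HIGHER_GROUP2)
    return n_up, n_unchanged, n_down


def assign_pathways(
    results: Sequence[DifferentialResult],
    pathways: Union[PathwayMap, Mapping[str, str]],
) -> dict[str, int]:
    """Count results per pathway label; unmapped genes fall under "unassigned".

    The counts (including "unassigned") always sum to the input length.
    """
    assignments = (
        pathways.assignments if isinstance(pathways, PathwayMap) else pathways
    )
    counts: dict[str, int] = {}
    for res in results:
        label = assignments.get(res.gene, UNASSIGNED_PATHWAY)
        counts[label] = counts.get(label, 0) + 1
    return counts
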