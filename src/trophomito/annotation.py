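"""Cross-referencing proteins against a mitochondrial gene inventory.

A protein counts as a "true" mitochondrial protein when its gene symbol —
after normalization — matches a MitoCarta-style inventory, either as a
primary symbol or as a synonym.  Matches are always reported under the
inventory's primary symbol so that downstream symbol-keyed joins (against
transcriptome tables) are deterministic.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .errors import ValidationError
from .types import AnnotatedCounts, AnnotationTable, ProteinCounts

logger = logging.getLogger(__name__)


def normalize_gene_symbol(symbol: str) -> str:
    """Uppercase a gene symbol and strip all whitespace.

    Raises :class:`ValidationError` on empty/blank input.
    """
    if symbol is None or not symbol.strip():
        raise ValidationError(f"empty gene symbol {symbol!r}")
    return "".join(symbol.split()).upper()


def annotate_mitochondrial(
    records: Sequence[ProteinCounts], annotation: AnnotationTable
) -> list[AnnotatedCounts]:
    """Flag each protein record as mitochondrial or not.

    Matching order: normalized primary symbols first, then synonyms.  A
    symbol that is the primary symbol of one entry and a synonym of another
    resolves to the primary-symbol entry; a symbol that is a synonym of
    several entries resolves to the first entry in file order (warned).
    Every input record appears exactly once in the output, in input order;
    no match is a valid outcome, not an error.
    """
    if len(annotation) == 0:
        raise ValidationError("annotation table is empty")

    primary: dict[str, str] = {}
    synonym: dict[str, str] = {}
    synonym_clashes: dict[str, list[str]] = {}
    for symbol, synonyms in annotation.entries:
        primary[symbol] = symbol
        for alias in synonyms:
            if alias in synonym:
                synonym_clashes.setdefault(alias, [synonym[alias]]).append(symbol)
            else:
                synonym[alias] = symbol  # first entry in file order wins

    annotated: list[AnnotatedCounts] = []
    for record in records:
        key = normalize_gene_symbol(record.gene)
        matched = primary.get(key)
        if matched is None:
            matched = synonym.get(key)
            if matched is not None and key in synonym_clashes:
                logger.warning(
                    "gene %s is a synonym of several inventory entries %s; "
                    "resolved to %s (first in file order)",
                    key,
                    synonym_clashes[key],
                    matched,
                )
        annotated.append(
            AnnotatedCounts(
                record=record,
                is_mitochondrial=matched is not None,
                matched_symbol=matched,
            )
        )
    return annotated
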