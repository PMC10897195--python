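"""Cohort-level aggregation and clinical-relevance stratifications.

Turns per-variant editability calls and improvement results into the
headline summary (counts and fractions per editing category, cross-tabbed
by mismatch type and molecular consequence) and applies the
clinical-relevance filters: number of distinct ClinVar submitters,
presence in a population-frequency table, guide-specificity (MIT score)
threshold, and tissue-restricted expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .editability import EditabilityCall
from .improvement import ImprovementResult
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

CATEGORIES = ("direct", "complementary", "improvable", "not_amendable")


@dataclass
class SummaryReport:
    """Counts per editing category, with mismatch x consequence breakdown."""

    total: int
    category_counts: Dict[str, int] = field(default_factory=dict)
    by_mismatch_consequence: Optional[pd.DataFrame] = None

    @property
    def fractions(self) -> Dict[str, float]:
        if self.total == 0:
            return {}
        return {k: v / self.total for k, v in self.category_counts.items()}


def tabulate(
    records: Sequence[VariantRecord],
    calls: Mapping[str, EditabilityCall],
    improvements: Optional[Mapping[str, ImprovementResult]] = None,
) -> SummaryReport:
    """Assign each record its primary category and tabulate.

    Precedence: direct > complementary > improvable > not amendable.  An
    improvement candidate only counts as improvable when an actual
    improvement result exists for it.  Direct + complementary on one record
    violates the editability invariant and raises.
    """
    improvements = improvements or {}
    counts = {c: 0 for c in CATEGORIES}
    rows = []
    for r in records:
        call = calls[r.record_id]
        call.validate()
        if call.dna_direct:
            cat = "direct"
        elif call.dna_complementary and r.record_id in improvements:
            # cannot happen for direct calls; complementary variants may
            # additionally be improvable, complementary editing wins
            cat = "complementary"
        elif call.dna_complementary:
            cat = "complementary"
        elif call.improvement_candidate and r.record_id in improvements:
            cat = "improvable"
        else:
            cat = "not_amendable"
        counts[cat] += 1
        rows.append(
            {
                "mismatch": r.mismatch,
                "consequence": r.consequence or "none",
                "category": cat,
            }
        )
    df = (
        pd.DataFrame(rows)
        .groupby(["mismatch", "consequence", "category"])
        .size()
        .rename("count")
        .reset_index()
        if rows
        else None
    )
    report = SummaryReport(len(records), counts, df)
    assert sum(counts.values()) == len(records)
    return report


def filter_by_submitters(
    records: Sequence[VariantRecord], k: int = 3
) -> List[VariantRecord]:
    """Keep records reported by at least ``k`` distinct submitters.

    A high submitter count is an indirect proxy for a variant being common.
    Records with no submitter data are dropped with a warning (unless k=0).
    """
    kept = []
    n_missing = 0
    for r in records:
        if r.n_submitters is None:
            if k == 0:
                kept.append(r)
            else:
                n_missing += 1
        elif r.n_submitters >= k:
            kept.append(r)
    if n_missing:
        logger.warning("%d records lack submitter counts; dropped", n_missing)
    return kept


def filter_by_frequency_presence(
    records: Sequence[VariantRecord],
    freq_table: Mapping[Tuple[str, int, str, str], float],
) -> List[VariantRecord]:
    """Keep records present in a population-frequency table with freq > 0."""
    return [
        r
        for r in records
        if freq_table.get((r.chrom, r.pos, r.ref, r.alt), 0.0) > 0.0
    ]


def filter_by_specificity(
    records: Sequence[VariantRecord],
    mit_table: Mapping[str, float],
    threshold: float = 50.0,
) -> List[VariantRecord]:
    """Keep records whose guide's MIT specificity score exceeds ``threshold``.

    The MIT score (0-100) summarizes genome-wide off-target potential of the
    guide; above 50 is considered acceptable for therapeutic use.  Missing
    scores drop the record (counted and logged).
    """
    kept = []
    n_missing = 0
    for r in records:
        score = mit_table.get(r.record_id)
        if score is None:
            n_missing += 1
            continue
        if not 0.0 <= score <= 100.0:
            raise ValueError(
                f"MIT score outside [0,100] for {r.record_id}: {score}"
            )
        if score > threshold:
            kept.append(r)
    if n_missing:
        logger.info("%d records lack MIT scores; dropped", n_missing)
    return kept


def tissue_genes(
    expr: pd.DataFrame,
    tissue: str,
    high: float = 10.0,
    other_avg: float = 10.0,
) -> Set[str]:
    """Genes highly expressed in one tissue and lowly expressed elsewhere.

    ``expr`` is a gene x tissue matrix in TPM.  Selected genes have strictly
    more than ``high`` TPM in ``tissue`` and a strict mean below
    ``other_avg`` over all other tissues; genes at exactly the threshold are
    rejected on both sides.
    """
    if tissue not in expr.columns:
        raise KeyError(f"unknown tissue: {tissue!r}")
    if (expr.values < 0).any():
        raise ValueError("expression values must be non-negative")
    if expr.index.duplicated().any():
        raise ValueError("gene identifiers must be unique")
    others = [c for c in expr.columns if c != tissue]
    mask = expr[tissue] > high
    if others:
        mask &= expr[others].mean(axis=1) < other_avg
    return set(expr.index[mask])
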