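"""The codon-improvement algorithm.

For missense/nonsense variants whose mismatch type cannot be reverted by
direct editing, the mutant codon can still be re-edited: every nonempty
subset of A->G / C->T edits of the mutant codon yields a novel codon, and
the novel amino acid may resemble the reference amino acid more closely
than the mutant one does.  The algorithm enumerates all edit subsets,
scores each novel amino acid against the reference with a pluggable scorer,
and keeps the best strictly-improving option, preferring fewer edits and
breaking remaining ties lexicographically on the novel codon.

Scorers:

* ``matrix`` mode — a substitution matrix (BLOSUM62 by default); candidate
  score is matrix(ref_aa, novel_aa), baseline matrix(ref_aa, mut_aa).
* ``site_table`` mode — SIFT-style per-site tolerance scores in [0, 1] for
  this particular protein position; candidates scoring at or below the
  tolerance floor (default 0.05, "deleterious") are dropped, and candidates
  with no table entry are skipped (tolerance predictors do not cover every
  substitution).

Mutant stop codons are special-cased: escaping a premature stop is always
preferable, so any non-stop candidate beats the baseline (site_table mode
uses baseline 0 and waives the floor).  Novel stop codons are always
dropped — creating a nonsense variant is never an improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from . import seqcore
from .seqcore import (
    ALL_CHEMISTRIES,
    A_TO_G,
    C_TO_T,
    STOP,
    EditOp,
    SubstitutionMatrix,
    blosum62,
    enumerate_edits,
    translate,
)
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

MODE_A_ONLY = "A_only"
MODE_C_ONLY = "C_only"
MODE_COMBINED = "combined"


@dataclass
class ScorerMode:
    """Scoring configuration for the improvement algorithm."""

    kind: str = "matrix"  # "matrix" | "site_table"
    matrix: Optional[SubstitutionMatrix] = None
    site_scores: Optional[Mapping[str, float]] = None
    tolerance_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("matrix", "site_table"):
            raise ValueError(f"unknown scorer kind: {self.kind!r}")
        if not 0.0 <= self.tolerance_floor < 1.0:
            raise ValueError(f"tolerance_floor outside [0,1): {self.tolerance_floor}")
        if self.kind == "matrix" and self.matrix is None:
            self.matrix = blosum62()
        if self.site_scores is not None:
            for aa, s in self.site_scores.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"site score outside [0,1] for {aa}: {s}")

    @classmethod
    def blosum(cls) -> "ScorerMode":
        return cls(kind="matrix", matrix=blosum62())

    @classmethod
    def site_table(
        cls, site_scores: Mapping[str, float], tolerance_floor: float = 0.05
    ) -> "ScorerMode":
        return cls(
            kind="site_table", site_scores=site_scores, tolerance_floor=tolerance_floor
        )


@dataclass
class ImprovementResult:
    """The chosen edit subset for one mutant codon."""

    ref_codon: str
    mut_codon: str
    novel_codon: str
    ref_aa: str
    mut_aa: str
    novel_aa: str
    edit_ops: FrozenSet[EditOp]
    mut_score: float
    novel_score: float
    record_id: Optional[str] = None
    protein_level_correction: bool = False
    ptm_warning: bool = False

    @property
    def n_edits(self) -> int:
        return len(self.edit_ops)

    @property
    def score_delta(self) -> float:
        return self.novel_score - self.mut_score

    @property
    def mode_label(self) -> str:
        chems = {(op.from_base, op.to_base) for op in self.edit_ops}
        if chems == {A_TO_G}:
            return MODE_A_ONLY
        if chems == {C_TO_T}:
            return MODE_C_ONLY
        return MODE_COMBINED


def _ptm_warning(mut_aa: str, novel_aa: str) -> bool:
    # phosphorylation-site loss (S/T/Y -> G/A/C) or lysine methylation/
    # acetylation loss (K -> R/G); surfaced as a warning only
    return (mut_aa in "STY" and novel_aa in "GAC") or (
        mut_aa == "K" and novel_aa in "RG"
    )


def improve_codon(
    ref_codon: str,
    mut_codon: str,
    scorer: ScorerMode,
    chemistries=ALL_CHEMISTRIES,
) -> Optional[ImprovementResult]:
    """Find the best strictly-improving edit subset of a mutant codon.

    Returns None when no candidate survives.  Selection: maximum score,
    then minimum number of edits, then lexicographically smallest novel
    codon.  Synonymous and stop-lost inputs are rejected — the algorithm is
    defined for missense and nonsense variants only.
    """
    ref_aa = translate(ref_codon)
    mut_aa = translate(mut_codon)
    if ref_codon == mut_codon:
        raise ValueError("ref and mut codons are identical")
    if ref_aa == STOP:
        raise ValueError("stop-lost variants are not improvement candidates")
    if mut_aa == ref_aa:
        raise ValueError("synonymous variants are not improvement candidates")

    mut_is_stop = mut_aa == STOP
    if scorer.kind == "matrix":
        assert scorer.matrix is not None
        baseline: float = scorer.matrix.score(ref_aa, mut_aa)
    else:
        assert scorer.site_scores is not None
        baseline = 0.0 if mut_is_stop else scorer.site_scores.get(mut_aa, 0.0)

    best: Optional[Tuple[float, int, str, FrozenSet[EditOp], str]] = None
    for ops, novel in enumerate_edits(mut_codon, chemistries):
        novel_aa = translate(novel)
        if novel_aa == STOP:
            continue
        if scorer.kind == "matrix":
            score: float = scorer.matrix.score(ref_aa, novel_aa)  # type: ignore[union-attr]
        else:
            if novel_aa not in scorer.site_scores:  # type: ignore[operator]
                continue
            score = scorer.site_scores[novel_aa]  # type: ignore[index]
            if not mut_is_stop and score <= scorer.tolerance_floor:
                continue
        if score <= baseline:
            continue
        key = (-score, len(ops), novel)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (score, len(ops), novel, ops, novel_aa)
    if best is None:
        return None
    score, _n, novel, ops, novel_aa = best
    return ImprovementResult(
        ref_codon=ref_codon,
        mut_codon=mut_codon,
        novel_codon=novel,
        ref_aa=ref_aa,
        mut_aa=mut_aa,
        novel_aa=novel_aa,
        edit_ops=ops,
        mut_score=baseline,
        novel_score=score,
        protein_level_correction=novel_aa == ref_aa,
        ptm_warning=_ptm_warning(mut_aa, novel_aa),
    )


def improve_variant(
    record: VariantRecord,
    scorer: ScorerMode,
    chemistries=ALL_CHEMISTRIES,
) -> Optional[ImprovementResult]:
    """Run the improvement algorithm on one variant's codons.

    The record must be an improvement candidate (missense/nonsense, not
    direct-editable) and carry codon context.
    """
    if record.codon is None or record.codon_index is None:
        raise ValueError(f"record {record.record_id} lacks codon context")
    if record.mismatch_tx in ("G>A", "T>C"):
        raise ValueError(
            f"record {record.record_id} is direct-editable, not an improvement candidate"
        )
    if record.consequence not in ("missense", "nonsense"):
        raise ValueError(
            f"record {record.record_id} has consequence {record.consequence!r}; "
            "only missense/nonsense variants are improvement candidates"
        )
    ref_codon = record.codon
    mut = list(ref_codon)
    mut[record.codon_index] = record.alt_tx
    mut_codon = "".join(mut)
    result = improve_codon(ref_codon, mut_codon, scorer, chemistries)
    if result is not None:
        result.record_id = record.record_id
    return result


@dataclass
class DeltaSummary:
    n: int
    mean_delta: float
    per_mode: Dict[str, int] = field(default_factory=dict)


def score_delta_distribution(
    results: Sequence[ImprovementResult],
) -> DeltaSummary:
    """Mean score improvement and per-chemistry-mode counts.

    All results must come from one scorer mode (matrix sentinels and
    site-table scores must never be averaged together); mutant-stop results
    under matrix mode carry sentinel baselines and are rejected here.
    """
    if not results:
        return DeltaSummary(0, float("nan"), {})
    for r in results:
        if r.mut_score <= seqcore.STOP_ESCAPE_SCORE:
            raise ValueError(
                "results contain matrix-mode stop sentinels; score deltas are "
                "only meaningful within site_table mode or among non-stop "
                "matrix results"
            )
    per_mode: Dict[str, int] = {MODE_A_ONLY: 0, MODE_C_ONLY: 0, MODE_COMBINED: 0}
    total = 0.0
    for r in results:
        per_mode[r.mode_label] += 1
        total += r.score_delta
    return DeltaSummary(len(results), total / len(results), per_mode)
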