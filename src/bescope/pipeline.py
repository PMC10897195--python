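"""End-to-end cohort analysis: the glue the drivers and tests share.

Runs the full sequence on a cohort (synthetic or parsed from files):
filtering cascade -> CDS context -> editability calls -> ADAR / PAM /
bystander context -> off-target census -> codon improvement -> summary
tables.  Per-record details are kept so recovery tests can compare every
planted attribute against the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .context import (
    AdarMotifResult,
    BystanderReport,
    PamHit,
    PredictorTable,
    adar_motif,
    annotate_bystander_pathogenicity,
    count_bystanders_dna,
    count_bystanders_rna,
    find_ngg_pams,
)
from .editability import DIRECT_TYPES, EditabilityCall, call_editability, mismatch_census
from .improvement import ImprovementResult, ScorerMode, improve_variant, score_delta_distribution
from .offtarget import OffTargetQuery, build_query, offtarget_census, zero_hit_fraction
from .summarize import (
    SummaryReport,
    filter_by_specificity,
    filter_by_submitters,
    tabulate,
    tissue_genes,
)
from .synthetic_data import EDITABLE_BASE, SyntheticCohort
from .variant_io import (
    CODING,
    GENE_NONCODING,
    FilterReport,
    VariantRecord,
    apply_exclusions,
    attach_cds_context,
    filter_pathogenic,
)


def mutant_window(record: VariantRecord) -> str:
    """The record's reference context window with the mutant allele at the
    target position."""
    if record.window is None or record.window_target is None:
        raise ValueError(f"record {record.record_id} has no context window")
    chars = list(record.window)
    chars[record.window_target] = record.alt_tx
    return "".join(chars)


@dataclass
class PipelineResult:
    records: List[VariantRecord]
    filter_reports: List[FilterReport]
    calls: Dict[str, EditabilityCall]
    census: Dict[str, int]
    adar: Dict[str, AdarMotifResult]
    pam_hits: Dict[str, List[PamHit]]
    rna_bystanders: Dict[str, BystanderReport]
    dna_bystanders: Dict[str, BystanderReport]
    offtarget_counts: Dict[str, int]
    improvements: Dict[str, ImprovementResult]
    n_improvement_candidates: int
    summary: SummaryReport
    n_submitter_high: int
    mit_kept_ids: Set[str]
    n_pam_in_range: int
    liver_genes: Set[str]
    brain_genes: Set[str]

    def metrics(self) -> Dict[str, float]:
        """Cohort-level headline numbers, on the paper-style scales
        (percentages in 0-100, means as plain values)."""
        by_id = {r.record_id: r for r in self.records}
        n = len(self.records)
        cats = self.summary.category_counts
        out: Dict[str, float] = {
            "n_pathogenic_snvs": n,
            "pct_direct_editable": 100.0 * cats.get("direct", 0) / n,
            "pct_complementary_editable": 100.0 * cats.get("complementary", 0) / n,
            "pct_improvable": 100.0 * cats.get("improvable", 0) / n,
        }
        out["pct_correctable"] = (
            out["pct_direct_editable"] + out["pct_complementary_editable"]
        )
        out["pct_amendable_any"] = out["pct_correctable"] + out["pct_improvable"]

        for region, key in ((CODING, "coding"), (GENE_NONCODING, "noncoding")):
            ga = [
                rid
                for rid, res in self.adar.items()
                if by_id[rid].region == region
            ]
            if ga:
                out[f"pct_adar_motif_{key}"] = 100.0 * sum(
                    self.adar[rid].motif_ok for rid in ga
                ) / len(ga)

        editable = [
            r
            for r in self.records
            if self.calls[r.record_id].dna_direct
            or self.calls[r.record_id].dna_complementary
        ]
        if editable:
            out["pct_pam_present"] = 100.0 * self.n_pam_in_range / len(editable)

        for mm, key in (("G>A", "g_a"), ("T>C", "t_c")):
            reps = [
                rep
                for rid, rep in self.rna_bystanders.items()
                if by_id[rid].mismatch_tx == mm and by_id[rid].region == CODING
            ]
            if reps:
                out[f"mean_rna_bystanders_{key}"] = float(
                    np.mean([r.n_bystanders for r in reps])
                )
                out[f"mean_rna_pathogenic_bystanders_{key}"] = float(
                    np.mean([r.n_predicted_pathogenic for r in reps])
                )
        dna_reps = [
            rep for rid, rep in self.dna_bystanders.items()
        ]
        if dna_reps:
            out["mean_dna_bystanders"] = float(
                np.mean([r.n_bystanders for r in dna_reps])
            )

        if self.offtarget_counts:
            out["pct_zero_offtarget"] = 100.0 * zero_hit_fraction(
                self.offtarget_counts
            )
        if self.n_pam_in_range:
            out["pct_mit_above_50"] = 100.0 * len(self.mit_kept_ids) / self.n_pam_in_range
        if self.improvements:
            delta = score_delta_distribution(list(self.improvements.values()))
            out["n_improvable"] = delta.n
            out["mean_improvement_delta"] = delta.mean_delta
            for mode, cnt in delta.per_mode.items():
                out[f"n_improvable_{mode}"] = cnt
        out["pct_submitter_high"] = 100.0 * self.n_submitter_high / n
        out["n_liver_genes"] = len(self.liver_genes)
        out["n_brain_genes"] = len(self.brain_genes)
        return out


def analyze_cohort(
    cohort: SyntheticCohort,
    offtarget_method: str = "seeded",
    submitter_threshold: int = 3,
    mit_threshold: float = 50.0,
) -> PipelineResult:
    """Run the full analysis on a synthetic cohort."""
    raw = list(cohort.records) + list(cohort.distractors)
    kept, rep_excl = apply_exclusions(raw)
    kept, rep_path = filter_pathogenic(kept)
    kept, rep_cds = attach_cds_context(kept, cohort.sequences)
    reports = [rep_excl, rep_path, rep_cds]

    calls = {r.record_id: call_editability(r) for r in kept}
    census = mismatch_census(kept)

    adar: Dict[str, AdarMotifResult] = {}
    pam_hits: Dict[str, List[PamHit]] = {}
    rna_bys: Dict[str, BystanderReport] = {}
    dna_bys: Dict[str, BystanderReport] = {}
    n_pam_in_range = 0
    for r in kept:
        call = calls[r.record_id]
        if r.window is None or r.window_target is None:
            continue
        win = mutant_window(r)
        t = r.window_target
        if r.mismatch_tx == "G>A":
            adar[r.record_id] = adar_motif(win, t)
        if call.dna_direct or call.dna_complementary:
            hits = find_ngg_pams(win, t)
            pam_hits[r.record_id] = hits
            b = EDITABLE_BASE[r.mismatch_tx]
            if hits:
                n_pam_in_range += 1
                rep = count_bystanders_dna(win, t, hits[0], b)
                dna_bys[r.record_id] = annotate_bystander_pathogenicity(
                    rep, r, cohort.predictor
                )
            if call.dna_direct:
                rep = count_bystanders_rna(win, t, b)
                rna_bys[r.record_id] = annotate_bystander_pathogenicity(
                    rep, r, cohort.predictor
                )

    queries: List[OffTargetQuery] = []
    for r in kept:
        if r.region == CODING and calls[r.record_id].dna_direct and r.tx_pos is not None:
            queries.append(build_query(r, cohort.sequences[r.transcript_id]))
    ot_counts = (
        offtarget_census(queries, cohort.subjects, method=offtarget_method)
        if queries
        else {}
    )

    improvements: Dict[str, ImprovementResult] = {}
    n_cand = 0
    for r in kept:
        call = calls[r.record_id]
        if not call.improvement_candidate or call.dna_complementary:
            continue
        if r.codon is None:
            continue
        n_cand += 1
        scorer = ScorerMode.site_table(cohort.site_scores.get(r.record_id, {}))
        res = improve_variant(r, scorer)
        if res is not None:
            improvements[r.record_id] = res

    summary = tabulate(kept, calls, improvements)
    n_high = len(filter_by_submitters(kept, submitter_threshold))
    pam_records = [r for r in kept if pam_hits.get(r.record_id)]
    mit_kept = {
        r.record_id
        for r in filter_by_specificity(pam_records, cohort.mit, mit_threshold)
    }
    liver = tissue_genes(cohort.expression, "liver") if len(cohort.expression) else set()
    brain = tissue_genes(cohort.expression, "brain") if len(cohort.expression) else set()

    return PipelineResult(
        records=kept,
        filter_reports=reports,
        calls=calls,
        census=census,
        adar=adar,
        pam_hits=pam_hits,
        rna_bystanders=rna_bys,
        dna_bystanders=dna_bys,
        offtarget_counts=ot_counts,
        improvements=improvements,
        n_improvement_candidates=n_cand,
        summary=summary,
        n_submitter_high=n_high,
        mit_kept_ids=mit_kept,
        n_pam_in_range=n_pam_in_range,
        liver_genes=liver,
        brain_genes=brain,
    )
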