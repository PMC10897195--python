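"""The codon-improvement algorithm: selection, tie-breaks, stop handling."""

import pytest

from bescope.improvement import (
    ImprovementResult,
    ScorerMode,
    improve_codon,
    improve_variant,
    score_delta_distribution,
)
from bescope.seqcore import A_TO_G, C_TO_T, blosum62, translate
from bescope.variant_io import CODING, VariantRecord


def test_matrix_mode_tyr_ser_to_phe():
    # mutant TCT (Ser) instead of TAT (Tyr): C->T yields TTT (Phe);
    # BLOSUM62(Y,S) = -2 < BLOSUM62(Y,F) = 3
    res = improve_codon("TAT", "TCT", ScorerMode.blosum())
    assert res is not None
    assert res.novel_codon == "TTT" and res.novel_aa == "F"
    assert res.n_edits == 1 and res.mode_label == "C_only"
    assert res.mut_score == -2 and res.novel_score == 3


def test_site_mode_his_gln_to_trp_three_edits():
    # mutant CAA (Gln) instead of CAC (His): tolerance table favors Trp, so
    # all three editable bases fire at once -> TGG
    scorer = ScorerMode.site_table({"Q": 0.05, "W": 0.25})
    res = improve_codon("CAC", "CAA", scorer)
    assert res is not None
    assert res.novel_codon == "TGG" and res.novel_aa == "W"
    assert res.n_edits == 3 and res.mode_label == "combined"
    assert res.mut_score == 0.05 and res.novel_score == 0.25


def test_stop_escape_to_trp():
    # mutant TAG stop: the single A->G edit gives TGG (Trp); escaping a
    # premature stop always beats retaining it
    res = improve_codon("TAC", "TAG", ScorerMode.blosum(), chemistries={A_TO_G})
    assert res is not None
    assert res.novel_codon == "TGG" and res.novel_aa == "W"
    assert res.n_edits == 1
    res2 = improve_codon("TAC", "TAG", ScorerMode.site_table({"W": 0.42}))
    assert res2 is not None and res2.score_delta == 0.42


def test_no_editable_base_returns_none():
    assert improve_codon("GCG", "GGG", ScorerMode.blosum()) is None


def test_novel_stop_candidates_dropped():
    # CAA under C->T only reaches TAA (stop): never an improvement
    assert (
        improve_codon("CAC", "CAA", ScorerMode.blosum(), chemistries={C_TO_T})
        is None
    )


def test_rejects_irrelevant_variants():
    with pytest.raises(ValueError):
        improve_codon("CTG", "CTG", ScorerMode.blosum())  # identical
    with pytest.raises(ValueError):
        improve_codon("CTA", "CTG", ScorerMode.blosum())  # synonymous
    with pytest.raises(ValueError):
        improve_codon("TAA", "CAA", ScorerMode.blosum())  # stop-lost


def test_site_mode_floor_drops_deleterious_candidates():
    scorer = ScorerMode.site_table({"S": 0.02, "F": 0.05})  # F at the floor
    assert improve_codon("TAT", "TCT", scorer) is None
    scorer = ScorerMode.site_table({"S": 0.02, "F": 0.051})
    res = improve_codon("TAT", "TCT", scorer)
    assert res is not None and res.novel_aa == "F"


def test_missing_site_entries_skip_candidates():
    assert improve_codon("TAT", "TCT", ScorerMode.site_table({})) is None


def _rec(ref_codon, codon_index, alt, consequence="missense"):
    return VariantRecord(
        record_id="r0",
        chrom="chr1",
        pos=1,
        ref=ref_codon[codon_index],
        alt=alt,
        transcript_id="TX1",
        cds_offset=10 + codon_index,
        region=CODING,
        consequence=consequence,
        clin_sig="Pathogenic",
        codon=ref_codon,
        codon_index=codon_index,
    )


def test_improve_variant_delegates():
    res = improve_variant(_rec("TAT", 1, "C"), ScorerMode.blosum())
    assert res is not None and res.novel_codon == "TTT"
    assert res.record_id == "r0"


def test_synonymous_restoration_flagged_at_codon_level():
    # ref TTA (Leu), mutant TCA (Ser): C->T restores TTA, the reference
    # codon itself — protein-level correction, allowed but flagged.  (This
    # situation only arises at codon level: the T>C variant itself is
    # direct-revertible, and no non-direct mismatch admits a restoring edit,
    # by exhaustive enumeration below.)
    res = improve_codon("TTA", "TCA", ScorerMode.blosum())
    assert res is not None
    assert res.novel_codon == "TTA" and res.novel_aa == "L"
    assert res.protein_level_correction

    from bescope.seqcore import ALL_CODONS, GENETIC_CODE, STOP, enumerate_edits

    for ref in ALL_CODONS:
        ref_aa = GENETIC_CODE[ref]
        if ref_aa == STOP:
            continue
        for idx in range(3):
            for alt in "ACGT":
                if alt == ref[idx] or f"{ref[idx]}>{alt}" in ("G>A", "T>C"):
                    continue
                mut = ref[:idx] + alt + ref[idx + 1 :]
                if GENETIC_CODE[mut] in (STOP, ref_aa):
                    continue
                for _ops, nov in enumerate_edits(mut):
                    assert GENETIC_CODE[nov] != ref_aa


def test_improve_variant_rejects_direct_editable():
    with pytest.raises(ValueError):
        improve_variant(_rec("GGG", 0, "A"), ScorerMode.blosum())  # G>A


def test_improve_variant_requires_codon_context():
    rec = _rec("TAT", 1, "C")
    rec.codon = None
    with pytest.raises(ValueError):
        improve_variant(rec, ScorerMode.blosum())


def test_ptm_warning_flag():
    # Ser -> Gly disrupts a potential phosphorylation site
    scorer = ScorerMode.site_table({"S": 0.02, "G": 0.5})
    res = improve_codon("CGC", "AGC", scorer)  # mut Ser; AGC -> GGC (Gly)
    assert res is not None and res.novel_aa == "G"
    assert res.ptm_warning


def test_never_worse_and_chemistry_restriction():
    """Over many random ref/mut pairs: strict improvement, no stop output,
    only legal edit ops applied to matching bases."""
    from bescope.seqcore import ALL_CODONS, GENETIC_CODE, STOP

    scorer = ScorerMode.blosum()
    n_checked = 0
    for ref in ALL_CODONS[::3]:
        for mut in ALL_CODONS[::5]:
            if ref == mut or GENETIC_CODE[ref] == STOP:
                continue
            if GENETIC_CODE[ref] == GENETIC_CODE[mut]:
                continue
            res = improve_codon(ref, mut, scorer)
            if res is None:
                continue
            n_checked += 1
            assert res.novel_score > res.mut_score
            assert translate(res.novel_codon) != STOP
            assert res.novel_codon != mut
            for op in res.edit_ops:
                assert (op.from_base, op.to_base) in {A_TO_G, C_TO_T}
                assert mut[op.position] == op.from_base
            assert res.mode_label in ("A_only", "C_only", "combined")
    assert n_checked > 50


def test_score_delta_distribution():
    def mk(delta, mode_ops):
        return ImprovementResult(
            ref_codon="TAT",
            mut_codon="TCT",
            novel_codon="TTT",
            ref_aa="Y",
            mut_aa="S",
            novel_aa="F",
            edit_ops=mode_ops,
            mut_score=0.1,
            novel_score=0.1 + delta,
        )

    from bescope.seqcore import EditOp

    a = frozenset({EditOp(1, "C", "T")})
    res = [mk(0.1, a), mk(0.3, a)]
    summary = score_delta_distribution(res)
    assert summary.n == 2
    assert summary.mean_delta == pytest.approx(0.2)
    assert summary.per_mode["C_only"] == 2
    empty = score_delta_distribution([])
    assert empty.n == 0 and empty.per_mode == {}


def test_score_delta_rejects_matrix_stop_sentinels():
    res = improve_codon("TAC", "TAG", ScorerMode.blosum())
    with pytest.raises(ValueError):
        score_delta_distribution([res])
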