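"""Synthetic-cohort generation and exact manifest recovery."""

import numpy as np
import pytest

from bescope.seqcore import GENETIC_CODE, STOP
from bescope.synthetic_data import (
    gen_transcriptome,
    generate_cohort,
    read_cohort,
    write_cohort,
)


# --- transcriptome ------------------------------------------------------------


def test_transcriptome_deterministic():
    a = gen_transcriptome(5, 300, seed=1)
    b = gen_transcriptome(5, 300, seed=1)
    assert a == b
    assert gen_transcriptome(5, 300, seed=2) != a


def test_transcriptome_is_valid_orf():
    for seq in gen_transcriptome(10, 240, seed=3).values():
        assert seq.startswith("ATG")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        assert GENETIC_CODE[codons[-1]] == STOP
        assert all(GENETIC_CODE[c] != STOP for c in codons[:-1])


@pytest.mark.parametrize("n,length", [(0, 300), (1, 99), (1, 200)])
def test_transcriptome_dimension_errors(n, length):
    with pytest.raises(ValueError):
        gen_transcriptome(n, length, seed=1)


# --- cohort determinism and file round trip -----------------------------------


def test_cohort_regeneration_is_identical():
    a = generate_cohort(120, seed=5)
    b = generate_cohort(120, seed=5)
    assert a.sequences == b.sequences
    assert a.truth.to_json() == b.truth.to_json()
    assert [r.__dict__ for r in a.records] == [r.__dict__ for r in b.records]
    assert a.mit == b.mit and a.freq == b.freq
    assert a.expression.equals(b.expression)


def test_cohort_file_round_trip(tmp_path):
    cohort = generate_cohort(80, seed=6)
    write_cohort(cohort, str(tmp_path))
    back = read_cohort(str(tmp_path))
    assert back.sequences == cohort.sequences
    assert len(back.records) == len(cohort.records)
    assert back.site_scores == {
        k: v for k, v in cohort.site_scores.items()
    }
    assert back.mit == cohort.mit
    assert back.truth.cohort["category_counts"] == cohort.truth.cohort["category_counts"]
    got = {r.record_id: r for r in back.records}
    for r in cohort.records:
        assert got[r.record_id].__dict__ == r.__dict__


def test_composition_infeasible_raises():
    from bescope.synthetic_data import DEFAULTS, _assign_roles, _default_composition, gen_variants

    plans = _default_composition(100, DEFAULTS)
    _assign_roles(plans, DEFAULTS, 1)
    tiny = gen_transcriptome(3, 240, seed=1)
    with pytest.raises(ValueError):
        gen_variants(tiny, plans, DEFAULTS, seed=1)


# --- exact recovery on the shared fixture ------------------------------------


def _resolved_category(res, rid):
    call = res.calls[rid]
    if call.dna_direct:
        return "direct"
    if call.dna_complementary:
        return "complementary"
    if call.improvement_candidate and rid in res.improvements:
        return "improvable"
    return "not_amendable"


def test_filter_cascade_recovers_distractor_counts(small_cohort, small_result):
    rep_excl, rep_path, rep_cds = small_result.filter_reports
    assert rep_excl.removed == {
        "downstream": 10,
        "upstream": 10,
        "no_sequence_alteration": 10,
        "no_consequence": 10,
        "misclassified_snv": 10,
        "mitochondrial": 10,
    }
    assert rep_path.removed["not_pathogenic"] == 100  # planted benign rows
    assert rep_path.removed["conflict_not_pathogenic"] == 30
    assert rep_cds.removed == {
        "cds_mismatch": 0,
        "missing_transcript": 0,
        "offset_out_of_range": 0,
    }
    assert len(small_result.records) == 400


def test_editability_categories_recover_manifest(small_cohort, small_result):
    truth = small_cohort.truth
    for rid, ent in truth.variants.items():
        assert _resolved_category(small_result, rid) == ent.category
    assert small_result.summary.category_counts == truth.cohort["category_counts"]


def test_adar_calls_recover_manifest(small_cohort, small_result):
    truth = small_cohort.truth
    n = 0
    for rid, ent in truth.variants.items():
        if ent.adar_ok is None or not ent.context_planted:
            continue
        assert small_result.adar[rid].motif_ok == ent.adar_ok
        n += 1
    assert n > 30


def test_pam_boundary_distances_recover(small_cohort, small_result):
    """Planted PAMs at 12/16 are accepted, decoys at 11/17 rejected."""
    truth = small_cohort.truth
    seen = set()
    for rid, ent in truth.variants.items():
        if ent.pam_distance is None or rid not in small_result.pam_hits:
            continue
        hits = small_result.pam_hits[rid]
        assert bool(hits) == ent.pam_in_range, (rid, ent.pam_distance)
        if hits:
            assert len(hits) == 1
            assert hits[0].distance == ent.pam_distance
        seen.add(ent.pam_distance)
    assert {11, 12, 16, 17} <= seen


def test_bystander_counts_recover(small_cohort, small_result):
    truth = small_cohort.truth
    n_rna = n_dna = 0
    for rid, ent in truth.variants.items():
        if ent.rna_bystanders is not None:
            rep = small_result.rna_bystanders[rid]
            assert rep.n_bystanders == ent.rna_bystanders
            assert rep.n_predicted_pathogenic == ent.rna_pathogenic
            n_rna += 1
        if ent.dna_bystanders is not None and rid in small_result.dna_bystanders:
            rep = small_result.dna_bystanders[rid]
            assert rep.n_bystanders == ent.dna_bystanders
            assert rep.n_predicted_pathogenic == ent.dna_pathogenic
            n_dna += 1
    assert n_rna > 50 and n_dna > 10


def test_bystander_pathogenic_fraction_near_planted_rate(small_cohort, small_result):
    """Mean pathogenic/bystander ratio approaches the planted Bernoulli rate
    (within 3 standard errors)."""
    truth = small_cohort.truth
    p = 0.26  # planted likely-pathogenic fraction for G>A bystanders
    flat = []
    for rid, ent in truth.variants.items():
        # coding only: non-coding bystanders have no predictor coverage
        if ent.mismatch == "G>A" and ent.region == "coding" and ent.rna_bystanders:
            rep = small_result.rna_bystanders[rid]
            flat.extend(
                [1] * rep.n_predicted_pathogenic
                + [0] * (rep.n_bystanders - rep.n_predicted_pathogenic)
            )
    assert len(flat) > 200
    se = np.sqrt(p * (1 - p) / len(flat))
    assert abs(np.mean(flat) - p) < 3 * se


def test_offtarget_census_recovers_planted_hits(small_cohort, small_result):
    truth = small_cohort.truth
    n_hits = n_zero = 0
    for rid, ent in truth.variants.items():
        if ent.offtarget_hits is None:
            continue
        assert small_result.offtarget_counts[rid] == ent.offtarget_hits
        if ent.offtarget_hits:
            n_hits += 1
        else:
            n_zero += 1
    assert n_hits > 0 and n_zero > 0
    # identities straddling the threshold: 0.829 decoys count zero
    decoys = [
        rid
        for rid, ent in truth.variants.items()
        if 0.829 in ent.offtarget_identities
    ]
    assert decoys
    assert all(small_result.offtarget_counts[rid] == 0 for rid in decoys)


def test_improvements_recover_planted_choices(small_cohort, small_result):
    truth = small_cohort.truth
    n = 0
    for rid, ent in truth.variants.items():
        if ent.improvable is None:
            continue
        got = small_result.improvements.get(rid)
        assert (got is not None) == ent.improvable
        if got is None:
            continue
        n += 1
        assert got.novel_codon == ent.expected_novel_codon
        assert got.novel_aa == ent.expected_novel_aa
        assert got.n_edits == ent.expected_n_edits
        assert got.mode_label == ent.expected_mode
        assert got.score_delta == pytest.approx(ent.planted_delta, abs=1e-9)
    assert n == truth.cohort["category_counts"]["improvable"]


def test_mit_filter_recovers_planted_pass_set(small_cohort, small_result):
    truth = small_cohort.truth
    for rid, ent in truth.variants.items():
        if ent.mit_pass is None:
            continue
        assert (rid in small_result.mit_kept_ids) == ent.mit_pass


def test_tissue_gene_selection_recovers_planted_sets(small_cohort, small_result):
    assert small_result.liver_genes == set(small_cohort.truth.cohort["liver_genes"])
    assert small_result.brain_genes == set(small_cohort.truth.cohort["brain_genes"])


def test_submitter_fraction_recovered(small_cohort, small_result):
    truth = small_cohort.truth
    expected = sum(
        1 for e in truth.variants.values() if e.n_submitters and e.n_submitters >= 3
    )
    assert small_result.n_submitter_high == expected
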