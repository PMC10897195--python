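"""ADAR motif, PAM discovery, bystander counting and annotation."""

import numpy as np
import pytest

from bescope.context import (
    PredictorTable,
    adar_motif,
    annotate_bystander_pathogenicity,
    count_bystanders_dna,
    count_bystanders_rna,
    find_ngg_pams,
)
from bescope.seqcore import reverse_complement
from bescope.variant_io import CODING, VariantRecord


# --- ADAR motif ---------------------------------------------------------------


def test_adar_motif_5prime_g_blocks():
    # ...TGA... with the A of TGA as the edited base: 5' neighbor is G
    seq = "CCTGACC"
    res = adar_motif(seq, 4)
    assert res.five_prime_base == "G"
    assert not res.motif_ok


def test_adar_motif_ok_for_non_g_neighbor():
    res = adar_motif("CCACC", 2)
    assert res.five_prime_base == "C"
    assert res.motif_ok


def test_adar_motif_boundary():
    res = adar_motif("ACGT", 0)
    assert res.five_prime_base is None
    assert not res.motif_ok
    assert res.at_boundary


# --- PAM discovery ------------------------------------------------------------


def _brute_force_pams(seq, t, lo=12, hi=16):
    """Independent scan: every trinucleotide, both orientations, distance
    filter, window bounds."""
    out = set()
    n = len(seq)
    for i in range(n - 2):
        if seq[i + 1 : i + 3] == "GG":  # NGG with N at i, downstream of t
            d = i - t - 1
            if lo <= d <= hi and i - hi - 1 >= 0 and i - lo <= n:
                out.add(("+", i, d, i - hi - 1, i - lo))
        if seq[i : i + 2] == "CC":  # CCN: NGG on the minus strand, N at i+2
            q = i + 2
            d = t - q - 1
            if lo <= d <= hi and q + lo + 1 >= 0 and q + hi + 2 <= n:
                out.add(("-", q, d, q + lo + 1, q + hi + 2))
    return out


def _as_tuples(hits):
    return {
        (h.strand, h.pam_start, h.distance, h.window_start, h.window_end)
        for h in hits
    }


def test_planted_agg_at_distance_14():
    t = 25
    seq = ["T"] * 60
    j = t + 15  # N of NGG at distance 14
    seq[j], seq[j + 1], seq[j + 2] = "A", "G", "G"
    seq = "".join(seq)
    hits = find_ngg_pams(seq, t)
    assert len(hits) == 1
    h = hits[0]
    assert (h.strand, h.distance) == ("+", 14)
    assert h.window_start <= t < h.window_end
    assert h.window_end - h.window_start == 5
    assert _as_tuples(hits) == _brute_force_pams(seq, t)


def test_poly_t_has_no_pam():
    assert find_ngg_pams("T" * 60, 30) == []


@pytest.mark.parametrize("d,expected", [(11, 0), (12, 1), (16, 1), (17, 0)])
def test_distance_boundaries(d, expected):
    t = 30
    seq = ["T"] * 70
    j = t + d + 1
    seq[j], seq[j + 1], seq[j + 2] = "A", "G", "G"
    assert len(find_ngg_pams("".join(seq), t)) == expected


def test_pam_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(42)
    for _ in range(300):
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=100))
        t = int(rng.integers(20, 80))
        assert _as_tuples(find_ngg_pams(seq, t)) == _brute_force_pams(seq, t)


def test_target_always_inside_window_fuzz():
    rng = np.random.default_rng(7)
    for _ in range(200):
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=80))
        t = int(rng.integers(0, 80))
        for h in find_ngg_pams(seq, t):
            assert h.window_start <= t < h.window_end


# --- bystanders ---------------------------------------------------------------


def test_rna_bystanders_counted_excluding_target():
    #           0123456789012345678901234567890
    seq = "TTTTTTTTTTATATTTTTTTATTTTTATTTT"
    t = 15  # a T; count surrounding A's within +/-10
    rep = count_bystanders_rna(seq, t, "A")
    expected = [i for i in range(5, 26) if i != t and seq[i] == "A"]
    assert rep.positions == expected
    assert rep.n_bystanders == len(expected)


def test_rna_bystanders_truncated_window():
    rep = count_bystanders_rna("AATAAA", 3, "A")
    assert rep.n_bystanders == 4
    assert count_bystanders_rna("GGGGG", 2, "A").n_bystanders == 0


def test_dna_bystanders_in_window():
    from bescope.context import PamHit

    seq = "TTTTTAATACTTTTT"
    hit = PamHit("+", 99, 14, 5, 10)  # window covers "AATAC"
    rep = count_bystanders_dna(seq, 8, hit, "A")  # target: the A before C
    assert rep.n_bystanders == 2  # the two non-target A's
    assert count_bystanders_dna(seq, 8, hit, "G").n_bystanders == 0
    with pytest.raises(ValueError):
        count_bystanders_dna("AAT", 1, PamHit("+", 9, 14, 0, 5), "A")


def test_dna_agrees_with_rna_on_same_positions():
    from bescope.context import PamHit

    rng = np.random.default_rng(3)
    for _ in range(50):
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=41))
        t = 20
        hit = PamHit("+", 99, 14, 18, 23)
        dna = count_bystanders_dna(seq, t, hit, "A")
        rna = count_bystanders_rna(seq, t, "A")
        assert set(dna.positions) == {
            p for p in rna.positions if 18 <= p < 23
        }


def test_bystanders_reverse_complement_symmetry():
    rng = np.random.default_rng(5)
    for _ in range(50):
        seq = "".join("ACGT"[k] for k in rng.integers(0, 4, size=41))
        t = int(rng.integers(0, 41))
        for base, comp in (("A", "T"), ("C", "G")):
            fwd = count_bystanders_rna(seq, t, base)
            rev = count_bystanders_rna(
                reverse_complement(seq), len(seq) - 1 - t, comp
            )
            assert fwd.n_bystanders == rev.n_bystanders
            assert {len(seq) - 1 - p for p in fwd.positions} == set(rev.positions)


# --- predictor annotation -----------------------------------------------------


def _coding_rec():
    return VariantRecord(
        record_id="r0",
        chrom="chr1",
        pos=100,
        ref="G",
        alt="A",
        transcript_id="TX1",
        cds_offset=50,
        region=CODING,
        consequence="missense",
        clin_sig="Pathogenic",
    )


def test_annotate_counts_pathogenic_bystanders():
    rec = _coding_rec()
    rep = count_bystanders_rna("A" * 21, 10, "A")
    assert rep.n_bystanders == 20
    # class 1 of the first 3 bystanders pathogenic, rest benign
    entries = {}
    for k, pos in enumerate(rep.positions):
        cls = "likely_pathogenic" if k == 1 else "likely_benign"
        entries[("TX1", 50 + pos - 10, "G")] = (0.9 if k == 1 else 0.1, cls)
    table = PredictorTable(entries)
    out = annotate_bystander_pathogenicity(rep, rec, table)
    assert out.n_predicted_pathogenic == 1
    assert out.n_predicted_pathogenic <= out.n_bystanders


def test_annotate_empty_table_counts_zero():
    rec = _coding_rec()
    rep = count_bystanders_rna("A" * 21, 10, "A")
    out = annotate_bystander_pathogenicity(rep, rec, PredictorTable({}))
    assert out.n_predicted_pathogenic == 0


def test_predictor_table_validation_and_tsv(tmp_path):
    with pytest.raises(ValueError):
        PredictorTable({("T", 1, "G"): (1.5, "likely_benign")})
    with pytest.raises(ValueError):
        PredictorTable({("T", 1, "G"): (0.5, "meh")})
    table = PredictorTable(
        {("TX1", 3, "G"): (0.9, "likely_pathogenic"),
         ("TX1", 4, "T"): (0.1, "likely_benign")}
    )
    path = tmp_path / "p.tsv"
    table.to_tsv(str(path))
    back = PredictorTable.from_tsv(str(path))
    assert back.lookup("TX1", 3, "G") == (0.9, "likely_pathogenic")
    assert back.lookup("TX1", 9, "G") is None
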