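"""Off-target query construction and local-alignment search."""

import math

import numpy as np
import pytest

from bescope.offtarget import (
    OffTargetQuery,
    build_query,
    offtarget_census,
    search_offtargets,
    zero_hit_fraction,
)
from bescope.seqcore import reverse_complement
from bescope.variant_io import CODING, VariantRecord


# --- independent dynamic-programming oracle ----------------------------------

GAP = -2


def _oracle_best(q, s):
    n, m = len(q), len(s)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    bh, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        row, prev = H[i], H[i - 1]
        qc = q[i - 1]
        for j in range(1, m + 1):
            sc = s[j - 1]
            if qc == "#" or sc == "#":
                sub = -10
            elif qc == sc:
                sub = 1
            else:
                sub = -1
            h = prev[j - 1] + sub
            if prev[j] + GAP > h:
                h = prev[j] + GAP
            if row[j - 1] + GAP > h:
                h = row[j - 1] + GAP
            if h < 0:
                h = 0
            row[j] = h
            if h > bh or (h == bh and h > 0 and (j < bj or (j == bj and i < bi))):
                bh, bi, bj = h, i, j
    if bh <= 0:
        return None
    i, j = bi, bj
    matches = cols = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        qc, sc = q[i - 1], s[j - 1]
        sub = -10 if "#" in (qc, sc) else (1 if qc == sc else -1)
        if H[i][j] == H[i - 1][j - 1] + sub:
            cols += 1
            matches += sub == 1
            i -= 1
            j -= 1
        elif H[i][j] == H[i - 1][j] + GAP:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return bh, j, bj, matches, cols


def oracle_search(qseq, subjects, min_identity=0.85, min_len=20):
    """Greedy best-first masked extraction, written independently."""
    floor = max(1, math.ceil(min_len * (2 * min_identity - 1)))
    hits = []
    for sid in sorted(subjects):
        for strand in "+-":
            s = list(subjects[sid] if strand == "+" else reverse_complement(subjects[sid]))
            for _ in range(25):
                aln = _oracle_best(qseq, "".join(s))
                if aln is None or aln[0] < floor:
                    break
                _score, ss, se, matches, cols = aln
                if cols >= min_len and matches / cols >= min_identity:
                    if strand == "+":
                        hits.append((sid, ss, se, cols, strand))
                    else:
                        hits.append((sid, len(s) - se, len(s) - ss, cols, strand))
                for p in range(ss, se):
                    s[p] = "#"
    return sorted(hits)


def _query(seq, rid="q0", source="SRC", start=0):
    return OffTargetQuery(
        record_id=rid,
        seq=seq,
        target_offset=len(seq) // 2,
        source_id=source,
        source_start=start,
        source_end=start + len(seq),
    )


def _rand_seq(rng, n):
    return "".join("ACGT"[k] for k in rng.integers(0, 4, size=n))


# --- query construction -------------------------------------------------------


def _rec(tx_pos, ref="G", alt="A"):
    return VariantRecord(
        record_id="r0",
        chrom="chr1",
        pos=1,
        ref=ref,
        alt=alt,
        transcript_id="TX1",
        cds_offset=tx_pos + 1,
        region=CODING,
        consequence="missense",
        clin_sig="Pathogenic",
        tx_pos=tx_pos,
    )


def test_build_query_mid_transcript():
    tx = "G" * 100
    q = build_query(_rec(50), tx)
    assert len(q.seq) == 41
    assert q.target_offset == 20
    assert q.seq[20] == "A"  # the mutant allele, not the reference
    assert q.seq.count("A") == 1


def test_build_query_truncated_at_start():
    q = build_query(_rec(5), "G" * 100)
    assert len(q.seq) == 26
    assert q.target_offset == 5


def test_build_query_requires_position():
    rec = _rec(5)
    rec.tx_pos = None
    with pytest.raises(ValueError):
        build_query(rec, "G" * 100)


# --- search -------------------------------------------------------------------


def test_exact_planted_duplicate_found():
    rng = np.random.default_rng(0)
    qseq = _rand_seq(rng, 41)
    subject = _rand_seq(rng, 50) + qseq + _rand_seq(rng, 50)
    hits = search_offtargets(_query(qseq), {"S1": subject})
    assert len(hits) == 1
    h = hits[0]
    assert (h.identity, h.aln_len, h.is_self) == (1.0, 41, False)
    assert (h.subject_start, h.subject_end) == (50, 91)


def test_low_identity_copy_rejected_and_matches_oracle():
    # 7 mismatches spread over 41 nt: full-copy identity 0.829 < 0.85, and
    # the best (greedy-first) alignment is the full copy, so no hit
    rng = np.random.default_rng(1)
    qseq = _rand_seq(rng, 41)
    seg = list(qseq)
    for off in (5, 11, 17, 23, 29, 35, 38):
        seg[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[off]]
    subject = _rand_seq(rng, 40) + "".join(seg) + _rand_seq(rng, 40)
    subjects = {"S1": subject}
    hits = search_offtargets(_query(qseq), subjects)
    assert hits == []
    assert oracle_search(qseq, subjects) == []


def test_self_hit_flagged_and_excluded():
    rng = np.random.default_rng(2)
    tx = _rand_seq(rng, 120)
    qseq = tx[40:81]
    q = _query(qseq, source="TX", start=40)
    hits = search_offtargets(q, {"TX": tx})
    assert len(hits) == 1 and hits[0].is_self
    counts = offtarget_census([q], {"TX": tx}, method="exhaustive")
    assert counts == {"q0": 0}
    assert zero_hit_fraction(counts) == 1.0


def test_hit_counts_monotone_in_thresholds():
    rng = np.random.default_rng(3)
    qseq = _rand_seq(rng, 41)
    subjects = {}
    for k, n_mm in enumerate([0, 2, 4, 6]):
        seg = list(qseq)
        for off in range(n_mm):
            p = 3 + 6 * off
            seg[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seg[p]]
        subjects[f"S{k}"] = _rand_seq(rng, 30) + "".join(seg) + _rand_seq(rng, 30)

    def n_hits(ident, mlen):
        return len(
            search_offtargets(_query(qseq), subjects, min_identity=ident, min_len=mlen)
        )

    for lo, hi in [(0.75, 0.85), (0.85, 0.95)]:
        assert n_hits(lo, 20) >= n_hits(hi, 20)
    for lo, hi in [(20, 30), (30, 41)]:
        assert n_hits(0.85, lo) >= n_hits(0.85, hi)


def test_search_matches_oracle_on_random_instances():
    rng = np.random.default_rng(2024)
    for trial in range(100):
        qseq = _rand_seq(rng, 41)
        subjects = {}
        for k in range(2):
            s = _rand_seq(rng, 80)
            if trial % 3 == k:  # plant a partial copy in some subjects
                n_mm = int(rng.integers(0, 6))
                seg = list(qseq)
                for off in rng.choice(41, size=n_mm, replace=False):
                    seg[off] = "ACGT"[int(rng.integers(4))]
                piece = "".join(seg)
                if trial % 2:
                    piece = reverse_complement(piece)
                s = s[:20] + piece + s[61:]
            subjects[f"S{k}"] = s
        got = sorted(
            (h.subject_id, h.subject_start, h.subject_end, h.aln_len, h.strand)
            for h in search_offtargets(_query(qseq), subjects)
        )
        assert got == oracle_search(qseq, subjects), f"trial {trial}"


def test_reverse_complement_subject_symmetry():
    rng = np.random.default_rng(9)
    qseq = _rand_seq(rng, 41)
    subject = _rand_seq(rng, 30) + qseq + _rand_seq(rng, 30)
    fwd = search_offtargets(_query(qseq), {"S": subject})
    rev = search_offtargets(_query(qseq), {"S": reverse_complement(subject)})
    assert len(fwd) == len(rev) == 1
    n = len(subject)
    assert (rev[0].subject_start, rev[0].subject_end) == (
        n - fwd[0].subject_end,
        n - fwd[0].subject_start,
    )
    assert rev[0].strand != fwd[0].strand


def test_seeded_census_finds_planted_copy():
    rng = np.random.default_rng(12)
    qseq = _rand_seq(rng, 41)
    subjects = {
        "S1": _rand_seq(rng, 30) + qseq + _rand_seq(rng, 30),
        "S2": _rand_seq(rng, 100),
    }
    counts = offtarget_census([_query(qseq)], subjects, method="seeded")
    assert counts == {"q0": 1}
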