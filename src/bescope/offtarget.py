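"""Guide-adhesion off-target search.

An RNA base editor's guide pairs with ~40 nt around the variant; any other
transcriptomic locus similar enough to that adhesion region can be edited
unintentionally.  The search takes the 41-nt window centred on the variant
(carrying the MUTANT allele, since the guide is designed against the
patient sequence), aligns it locally against every subject transcript and
its reverse complement, and reports alignments with >= 85% identity over
>= 20 columns as off-target sites.  The alignment covering the query's own
source locus is flagged ``is_self`` and excluded from counts.

Alignment engine: Smith-Waterman with match +1 / mismatch -1 / gap -2
(linear), identity = matches / alignment columns (gap columns included in
the denominator).  Per subject and orientation, alignments are extracted
greedily best-score-first with masking (Waterman-Eggert style) until the
best remaining score drops below the minimum any passing hit could have.
For transcriptome-scale censuses an exact k-mer seed (default k=13) decides
which subjects are aligned at all; any alignment passing the thresholds
with a >= k exact run is guaranteed to be seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from numba import njit

from .seqcore import reverse_complement
from .variant_io import VariantRecord

MATCH = 1
MISMATCH = -1
GAP = -2
#: encoding for masked-out positions; scores -10 against everything so no
#: alignment survives crossing a masked region
MASK_CODE = 4

_ENC = np.full(256, MASK_CODE, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


@njit(cache=True)
def _sw_fill(q, s, match, mismatch, gap):  # pragma: no cover - jitted
    n = q.shape[0]
    m = s.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if q[i - 1] >= 4 or s[j - 1] >= 4:
                sub = -10
            elif q[i - 1] == s[j - 1]:
                sub = match
            else:
                sub = mismatch
            h = H[i - 1, j - 1] + sub
            up = H[i - 1, j] + gap
            if up > h:
                h = up
            left = H[i, j - 1] + gap
            if left > h:
                h = left
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best or (h == best and h > 0 and (j < bj or (j == bj and i < bi))):
                best = h
                bi = i
                bj = j
    return H, best, bi, bj


@dataclass
class LocalAlignment:
    score: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    cols: int

    @property
    def identity(self) -> float:
        return self.matches / self.cols if self.cols else 0.0


def _traceback(H: np.ndarray, q: np.ndarray, s: np.ndarray, bi: int, bj: int) -> LocalAlignment:
    """Deterministic traceback: diagonal preferred over up over left."""
    i, j = bi, bj
    matches = 0
    cols = 0
    score = int(H[bi, bj])
    while i > 0 and j > 0 and H[i, j] > 0:
        if q[i - 1] >= 4 or s[j - 1] >= 4:
            sub = -10
        elif q[i - 1] == s[j - 1]:
            sub = MATCH
        else:
            sub = MISMATCH
        if H[i, j] == H[i - 1, j - 1] + sub:
            if sub == MATCH:
                matches += 1
            cols += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + GAP:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return LocalAlignment(score, i, bi, j, bj, matches, cols)


def best_local_alignment(q: np.ndarray, s: np.ndarray) -> Optional[LocalAlignment]:
    H, best, bi, bj = _sw_fill(q, s, MATCH, MISMATCH, GAP)
    if best <= 0:
        return None
    return _traceback(H, q, s, bi, bj)


# --- query construction -------------------------------------------------------


@dataclass
class OffTargetQuery:
    """The guide-adhesion window around one variant (mutant allele)."""

    record_id: str
    seq: str
    target_offset: int
    source_id: str
    source_start: int  # 0-based half-open interval on the source transcript
    source_end: int
    cds_offset: Optional[int] = None


def build_query(
    record: VariantRecord, transcript_seq: str, flank: int = 20
) -> OffTargetQuery:
    """Build the adhesion query: ``flank`` nt each side plus the variant base.

    The query carries the mutant (alt) allele at the variant position and is
    truncated at transcript ends with the target offset adjusted.
    """
    if record.tx_pos is None:
        raise ValueError(f"record {record.record_id} has no transcript position")
    pos = record.tx_pos
    if not 0 <= pos < len(transcript_seq):
        raise ValueError(
            f"record {record.record_id}: position {pos} outside transcript"
        )
    start = max(0, pos - flank)
    end = min(len(transcript_seq), pos + flank + 1)
    seq = list(transcript_seq[start:end])
    seq[pos - start] = record.alt_tx
    return OffTargetQuery(
        record_id=record.record_id,
        seq="".join(seq),
        target_offset=pos - start,
        source_id=record.transcript_id,
        source_start=start,
        source_end=end,
        cds_offset=record.cds_offset,
    )


# --- search -------------------------------------------------------------------


@dataclass
class OffTargetHit:
    """One reported off-target site (forward subject coordinates)."""

    subject_id: str
    subject_start: int
    subject_end: int
    identity: float
    aln_len: int
    is_self: bool
    strand: str = "+"


def _min_passing_score(min_identity: float, min_len: int) -> int:
    # a passing alignment has >= min_len columns of which a fraction
    # >= min_identity are +1 matches and the rest at worst -1
    return max(1, math.ceil(min_len * (2.0 * min_identity - 1.0)))


def _search_one_strand(
    q_enc: np.ndarray,
    subject_seq: str,
    strand: str,
    min_identity: float,
    min_len: int,
    max_rounds: int = 25,
) -> List[Tuple[int, int, float, int]]:
    """Greedy masked extraction; returns (start, end, identity, cols) in
    forward subject coordinates for alignments passing both thresholds."""
    seq = subject_seq if strand == "+" else reverse_complement(subject_seq)
    s_enc = encode(seq)
    floor = _min_passing_score(min_identity, min_len)
    out = []
    n = len(seq)
    for _ in range(max_rounds):
        aln = best_local_alignment(q_enc, s_enc)
        if aln is None or aln.score < floor:
            break
        if aln.cols >= min_len and aln.identity >= min_identity:
            if strand == "+":
                out.append((aln.s_start, aln.s_end, aln.identity, aln.cols))
            else:
                out.append((n - aln.s_end, n - aln.s_start, aln.identity, aln.cols))
        s_enc[aln.s_start : aln.s_end] = MASK_CODE
    return out


def search_offtargets(
    query: OffTargetQuery,
    subjects: Mapping[str, str],
    min_identity: float = 0.85,
    min_len: int = 20,
    method: str = "exhaustive",
    seed_k: int = 13,
) -> List[OffTargetHit]:
    """Local-align the query against each subject and its reverse complement.

    ``method="seeded"`` restricts the alignment to subjects sharing an exact
    ``seed_k``-mer with the query (either orientation).  Hits are returned
    in deterministic (subject_id, subject_start) order; the hit covering the
    query's own source locus is flagged ``is_self``.
    """
    if not subjects:
        raise ValueError("subjects must be nonempty")
    if method not in ("exhaustive", "seeded"):
        raise ValueError(f"unknown method: {method!r}")
    q_enc = encode(query.seq)
    seeds: Optional[Set[str]] = None
    if method == "seeded":
        seeds = _kmers_both_strands(query.seq, seed_k)
    hits: List[OffTargetHit] = []
    for sid in sorted(subjects):
        sseq = subjects[sid]
        if seeds is not None and not _has_seed(sseq, seeds, seed_k):
            continue
        for strand in "+-":
            for start, end, ident, cols in _search_one_strand(
                q_enc, sseq, strand, min_identity, min_len
            ):
                is_self = (
                    sid == query.source_id
                    and start < query.source_end
                    and end > query.source_start
                )
                hits.append(
                    OffTargetHit(sid, start, end, ident, cols, is_self, strand)
                )
    hits.sort(key=lambda h: (h.subject_id, h.subject_start, h.strand))
    return hits


def _kmers_both_strands(seq: str, k: int) -> Set[str]:
    rc = reverse_complement(seq)
    return {seq[i : i + k] for i in range(len(seq) - k + 1)} | {
        rc[i : i + k] for i in range(len(rc) - k + 1)
    }


def _has_seed(subject: str, query_kmers: Set[str], k: int) -> bool:
    return any(subject[i : i + k] in query_kmers for i in range(len(subject) - k + 1))


def offtarget_census(
    queries: Sequence[OffTargetQuery],
    subjects: Mapping[str, str],
    min_identity: float = 0.85,
    min_len: int = 20,
    method: str = "seeded",
    seed_k: int = 13,
) -> Dict[str, int]:
    """Per-query non-self hit counts over a shared subject set.

    With ``method="seeded"`` a k-mer index of the subjects is built once and
    each query is aligned only against subjects sharing an exact seed.
    """
    index: Optional[Dict[str, Set[str]]] = None
    if method == "seeded":
        index = {}
        for sid, sseq in subjects.items():
            for i in range(len(sseq) - seed_k + 1):
                index.setdefault(sseq[i : i + seed_k], set()).add(sid)
    counts: Dict[str, int] = {}
    for query in queries:
        if index is not None:
            cand_ids: Set[str] = set()
            for kmer in _kmers_both_strands(query.seq, seed_k):
                cand_ids |= index.get(kmer, set())
            cand = {sid: subjects[sid] for sid in cand_ids}
            if not cand:
                counts[query.record_id] = 0
                continue
            hits = search_offtargets(
                query, cand, min_identity, min_len, method="exhaustive"
            )
        else:
            hits = search_offtargets(
                query, subjects, min_identity, min_len, method="exhaustive"
            )
        counts[query.record_id] = sum(1 for h in hits if not h.is_self)
    return counts


def zero_hit_fraction(counts: Mapping[str, int]) -> float:
    """Fraction of queries with zero non-self off-target hits."""
    if not counts:
        return float("nan")
    return sum(1 for c in counts.values() if c == 0) / len(counts)
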