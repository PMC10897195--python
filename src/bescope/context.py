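"""Sequence-context analysis around a target base.

Covers the three context questions that decide whether a base editor can be
aimed at a variant cleanly:

* the ADAR 5'-neighbor motif — endogenous ADAR recruitment prefers the
  absence of a G immediately 5' of the edited A;
* NGG PAM discovery for S. pyogenes Cas9 DNA editors, with the PAM required
  12-16 nt away from the target and the associated 5-base editing window;
* bystander enumeration — same-type bases near the target that the
  deaminase may also hit, within +/-10 nt for RNA editors (the guide-pairing
  region) or within the PAM editing window for DNA editors — plus
  pathogenicity annotation of those bystanders from a pluggable
  missense-predictor table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .variant_io import VariantRecord

logger = logging.getLogger(__name__)

#: sense-strand alt implied by deaminating a given sense-strand base.
#: A and C are edited directly (A->G, C->T); T and G are edited through the
#: complementary strand (T->C via antisense A->G, G->A via antisense C->T).
IMPLIED_ALT = {"A": "G", "C": "T", "T": "C", "G": "A"}


@dataclass
class AdarMotifResult:
    """5'-neighbor inspection for an edited A. motif_ok iff the neighbor
    exists and is not G."""

    five_prime_base: Optional[str]
    motif_ok: bool
    at_boundary: bool = False


def adar_motif(seq: str, target_index: int) -> AdarMotifResult:
    """Evaluate the ADAR motif at ``seq[target_index]`` (the edited A)."""
    if not 0 <= target_index < len(seq):
        raise IndexError(f"target_index {target_index} outside sequence")
    if target_index == 0:
        return AdarMotifResult(None, motif_ok=False, at_boundary=True)
    neighbor = seq[target_index - 1]
    return AdarMotifResult(neighbor, motif_ok=neighbor != "G")


@dataclass
class PamHit:
    """One NGG protospacer-adjacent motif near the target.

    ``strand`` is relative to the supplied sequence; ``pam_start`` is the
    0-based index of the N of NGG (in supplied-sequence coordinates for both
    strands); ``distance`` is the number of nucleotides between the target
    base and the nearest base of the PAM trinucleotide; the half-open
    editing window is the 5 protospacer positions spanning distances 12-16
    from the PAM, which contains the target by construction.
    """

    strand: str
    pam_start: int
    distance: int
    window_start: int
    window_end: int


def find_ngg_pams(
    seq: str,
    target_index: int,
    distance_range: Tuple[int, int] = (12, 16),
    pam: str = "NGG",
) -> List[PamHit]:
    """Scan both orientations for NGG PAMs 12-16 nt from the target.

    On the + orientation the PAM lies downstream of the target
    (``distance = pam_start - target_index - 1``); on the − orientation the
    PAM appears as CCN upstream of the target, mirrored.  Hits whose editing
    window would fall outside the sequence are discarded.
    """
    if pam != "NGG":
        raise ValueError("only the NGG motif is supported")
    if not 0 <= target_index < len(seq):
        raise IndexError(f"target_index {target_index} outside sequence")
    lo, hi = distance_range
    if not 0 < lo <= hi:
        raise ValueError(f"bad distance range: {distance_range}")
    n = len(seq)
    hits: List[PamHit] = []
    for d in range(lo, hi + 1):
        # + orientation: N at target + d + 1, GG right after
        j = target_index + d + 1
        if j + 2 < n and seq[j + 1] == "G" and seq[j + 2] == "G":
            w_start, w_end = j - hi - 1, j - lo
            if w_start >= 0 and w_end <= n:
                hits.append(PamHit("+", j, d, w_start, w_end))
        # − orientation: CCN on the supplied strand, N at target - d - 1
        q = target_index - d - 1
        if q - 2 >= 0 and seq[q - 2] == "C" and seq[q - 1] == "C":
            w_start, w_end = q + lo + 1, q + hi + 2
            if w_start >= 0 and w_end <= n:
                hits.append(PamHit("-", q, d, w_start, w_end))
    for h in hits:
        assert h.window_start <= target_index < h.window_end
    hits.sort(key=lambda h: (h.distance, h.strand))
    return hits


@dataclass
class BystanderReport:
    """Same-type editable bases near a target.

    ``positions`` are sequence indices (target excluded);
    ``n_predicted_pathogenic`` is filled in by
    :func:`annotate_bystander_pathogenicity`.
    """

    editable_base: str
    target_index: int
    positions: List[int] = field(default_factory=list)
    n_predicted_pathogenic: int = 0

    @property
    def n_bystanders(self) -> int:
        return len(self.positions)


def count_bystanders_rna(
    seq: str, target_index: int, editable_base: str, flank: int = 10
) -> BystanderReport:
    """Count editable bases within ``flank`` nt either side of the target.

    The window is truncated at sequence ends; the target itself is never
    counted.
    """
    if editable_base not in "ACGT":
        raise ValueError(f"bad editable base: {editable_base!r}")
    if not 0 <= target_index < len(seq):
        raise IndexError(f"target_index {target_index} outside sequence")
    lo = max(0, target_index - flank)
    hi = min(len(seq), target_index + flank + 1)
    positions = [
        i for i in range(lo, hi) if i != target_index and seq[i] == editable_base
    ]
    return BystanderReport(editable_base, target_index, positions)


def count_bystanders_dna(
    seq: str, target_index: int, hit: PamHit, editable_base: str
) -> BystanderReport:
    """Count editable bases inside a PAM hit's 5-base editing window."""
    if editable_base not in "ACGT":
        raise ValueError(f"bad editable base: {editable_base!r}")
    if hit.window_start < 0 or hit.window_end > len(seq):
        raise ValueError("editing window outside sequence bounds")
    positions = [
        i
        for i in range(hit.window_start, hit.window_end)
        if i != target_index and seq[i] == editable_base
    ]
    return BystanderReport(editable_base, target_index, positions)


class PredictorTable:
    """Per-substitution pathogenicity predictions (AlphaMissense-style).

    Keyed by (transcript_id, 1-based CDS offset, alt base); values are a
    score in [0, 1] and a class in {likely_benign, ambiguous,
    likely_pathogenic}.
    """

    CLASSES = ("likely_benign", "ambiguous", "likely_pathogenic")

    def __init__(
        self, entries: Mapping[Tuple[str, int, str], Tuple[float, str]]
    ) -> None:
        for key, (score, cls) in entries.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score outside [0,1] for {key}: {score}")
            if cls not in self.CLASSES:
                raise ValueError(f"unknown class for {key}: {cls!r}")
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def lookup(
        self, transcript_id: str, cds_offset: int, alt: str
    ) -> Optional[Tuple[float, str]]:
        return self._entries.get((transcript_id, cds_offset, alt))

    @classmethod
    def from_tsv(cls, path: str) -> "PredictorTable":
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
        entries = {
            (str(r.transcript_id), int(r.cds_offset), str(r.alt)): (
                float(r.score),
                str(getattr(r, "cls", getattr(r, "class_", "likely_benign"))),
            )
            for r in df.rename(columns={"class": "cls"}).itertuples()
        }
        return cls(entries)

    def to_tsv(self, path: str) -> None:
        rows = [
            {
                "transcript_id": t,
                "cds_offset": o,
                "alt": a,
                "score": s,
                "class": c,
            }
            for (t, o, a), (s, c) in sorted(self._entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def annotate_bystander_pathogenicity(
    report: BystanderReport,
    record: VariantRecord,
    table: PredictorTable,
) -> BystanderReport:
    """Annotate each bystander with its predicted post-edit pathogenicity.

    Each bystander position implies a fixed alteration (A->G / C->T on the
    edited strand, i.e. :data:`IMPLIED_ALT` on the sense strand); positions
    absent from the predictor table count as not pathogenic and are logged
    (missense predictors only cover amino-acid-changing alterations).
    """
    if record.cds_offset is None:
        if report.positions:
            logger.info(
                "record %s has no CDS context; bystanders not annotated",
                record.record_id,
            )
        return replace(report, n_predicted_pathogenic=0)
    n_path = 0
    n_missing = 0
    alt = IMPLIED_ALT[report.editable_base]
    for pos in report.positions:
        offset = record.cds_offset + (pos - report.target_index)
        entry = table.lookup(record.transcript_id, offset, alt)
        if entry is None:
            n_missing += 1
        elif entry[1] == "likely_pathogenic":
            n_path += 1
    if n_missing:
        logger.debug(
            "record %s: %d bystander positions missing from predictor table",
            record.record_id,
            n_missing,
        )
    return replace(report, n_predicted_pathogenic=n_path)
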