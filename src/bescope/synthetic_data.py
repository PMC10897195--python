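"""Seeded synthetic cohorts with a ground-truth manifest.

The generator emulates every input the pipeline consumes — a toy
transcriptome, a ClinVar-style variant table (with filter-fodder distractor
rows), a per-submitter VCF, AlphaMissense-style predictor and SIFT-style
site-score tables, MIT guide-specificity scores, allele frequencies and a
gene x tissue expression matrix — and records every planted property in a
:class:`SyntheticTruth` manifest so recovery tests can be exact.

Planted attributes are constructed, not sampled-then-measured: the ADAR
5'-neighbor, PAM placement (including out-of-range decoys at 11/17 nt),
bystander counts, off-target duplicates (with identities straddling the 85%
threshold) and improvable codon set-ups are all written into the sequence
so that each attribute holds by construction.  Around the plants:

* a variant's +/-10 nt bystander zone is filled without its editable base,
  so the planted bystander count is the true count;
* the PAM-eligible band (10-21 nt from the target) is kept free of GG/CC
  dinucleotides, so the planted PAM is the only one in range;
* a deduplication pass rewrites filler bases until no unintended 13-mer is
  shared between any off-target query window and any subject transcript,
  so the seeded off-target census finds exactly the planted duplicates.

Default composition parameters reproduce a pathogenic-SNV cohort of the
shape reported for ClinVar: ~30% direct-editable (G>A + T>C), ~29%
complementary-editable (C>T + A>G), ADAR-motif fractions of 69% (coding)
and 58% (non-coding), PAM presence 30%, MIT>50 in 77%, a 91% zero-off-target
rate, ~4% improvable with an A-only/C-only/combined split of roughly
77:22:1, and a mean site-score improvement of 0.22.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .context import IMPLIED_ALT, PredictorTable
from .editability import COMPLEMENTARY_TYPES, DIRECT_TYPES, MISMATCH_TYPES
from .seqcore import (
    ALL_CODONS,
    A_TO_G,
    C_TO_T,
    GENETIC_CODE,
    SENSE_CODONS,
    STOP,
    STOP_CODONS,
    EditOp,
    enumerate_edits,
    reverse_complement,
)
from .variant_io import CODING, GENE_NONCODING, VariantRecord

OTHER_TYPES = tuple(
    mm for mm in MISMATCH_TYPES if mm not in DIRECT_TYPES + COMPLEMENTARY_TYPES
)

#: sense-strand base hit by the deaminase for each editable mismatch type
EDITABLE_BASE = {"G>A": "A", "T>C": "C", "C>T": "T", "A>G": "G"}

_OTHER8_SHARE_CODING = 1.0 - (0.198 + 0.069 + 0.215 + 0.076)
_OTHER8_SHARE_NONCODING = 1.0 - (0.350 + 0.071 + 0.215 + 0.076)

DEFAULTS: Dict[str, object] = {
    "coding_fraction": 0.81,
    "coding_mismatch": {
        "G>A": 0.198,
        "T>C": 0.069,
        "C>T": 0.215,
        "A>G": 0.076,
        **{mm: _OTHER8_SHARE_CODING / 8 for mm in OTHER_TYPES},
    },
    "noncoding_mismatch": {
        "G>A": 0.350,
        "T>C": 0.071,
        "C>T": 0.215,
        "A>G": 0.076,
        **{mm: _OTHER8_SHARE_NONCODING / 8 for mm in OTHER_TYPES},
    },
    "coding_consequence": {
        "missense": 0.602,
        "nonsense": 0.377,
        "synonymous": 0.007,
        "initiator_codon": 0.012,
        "stop_lost": 0.002,
    },
    "noncoding_consequence": {"intron": 0.70, "splice": 0.15, "UTR": 0.15},
    "adar_ok": {CODING: 0.69, GENE_NONCODING: 0.58},
    "pam_fraction": 0.30,
    "pam_decoy_fraction": 0.05,
    "pam_distance_range": (12, 16),
    "pam_decoy_distances": (11, 17),
    "rna_bystander_p": {"A": 4.6 / 20, "C": 5.3 / 20},
    "dna_bystander_mean": {"G>A": 0.9, "T>C": 1.0, "C>T": 0.6, "A>G": 1.2},
    "pathogenic_fraction": {"G>A": 0.26, "T>C": 0.19, "C>T": 0.33, "A>G": 0.25},
    "offtarget_hit_fraction": 0.09,
    "offtarget_decoy_fraction": 0.04,
    "offtarget_identity_cycle": (1.0, 0.902, 0.854),
    "improvable_fraction": 0.041,
    "improvable_nonsense_share": 0.296,
    "improvable_mode_split": {"A_only": 0.766, "C_only": 0.222, "combined": 0.012},
    "delta_range": (0.07, 0.37),
    "mit_pass_fraction": 0.77,
    "submitter_high_fraction": 0.194,
    "gnomad_presence_fraction": 0.24,
    "conflict_kept_fraction": 0.05,
    "benign_distractor_fraction": 0.25,
    "n_exclusion_distractors": 10,  # per exclusion rule
    "n_conflict_dropped": 30,
    "tissues": (
        "liver",
        "brain",
        "heart",
        "lung",
        "kidney",
        "muscle",
        "skin",
        "blood",
        "pancreas",
        "spleen",
    ),
    "n_liver_specific": 60,
    "n_brain_specific": 300,
    "n_expression_decoys": 5,
    "transcript_length": 240,
    "noncoding_length": 150,
    "seed_k": 13,
}

_TARGET_CODON_SLOT = 40  # codon index of mid-placed coding variants
_NC_TARGET = 75  # target index in non-coding context sequences

_MISMATCH_OFFSETS = {
    # planted duplicate mismatch positions within the 41-nt segment; passing
    # identities keep a >=13 nt exact run, the sub-threshold decoy does not
    1.0: (),
    0.902: (3, 8, 13, 18),
    0.854: (2, 5, 8, 11, 14, 17),
    0.829: (5, 11, 17, 23, 29, 35, 38),
}


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


# --- codon set-up search ------------------------------------------------------


@lru_cache(maxsize=None)
def codon_setups(mismatch: str, consequence: str) -> Tuple[Tuple[str, int, str], ...]:
    """All (ref_codon, codon_index, alt) triples realising a mismatch type
    with a given molecular consequence."""
    ref_base, alt = mismatch.split(">")
    out: List[Tuple[str, int, str]] = []
    if consequence == "initiator_codon":
        for idx, b in enumerate("ATG"):
            if b == ref_base:
                out.append(("ATG", idx, alt))
        return tuple(out)
    for ref in ALL_CODONS:
        ref_aa = GENETIC_CODE[ref]
        for idx in range(3):
            if ref[idx] != ref_base:
                continue
            mut = ref[:idx] + alt + ref[idx + 1 :]
            mut_aa = GENETIC_CODE[mut]
            ok = (
                (consequence == "missense" and STOP not in (ref_aa, mut_aa) and ref_aa != mut_aa)
                or (consequence == "nonsense" and ref_aa != STOP and mut_aa == STOP)
                or (consequence == "synonymous" and ref_aa == mut_aa and ref_aa != STOP)
                or (consequence == "stop_lost" and ref_aa == STOP and mut_aa != STOP)
            )
            if ok:
                out.append((ref, idx, alt))
    return tuple(out)


def _mode_of(ops: FrozenSet[EditOp]) -> str:
    chems = {(op.from_base, op.to_base) for op in ops}
    if chems == {A_TO_G}:
        return "A_only"
    if chems == {C_TO_T}:
        return "C_only"
    return "combined"


@lru_cache(maxsize=None)
def improvable_missense_setups(
    mismatch: str, mode: str
) -> Tuple[Tuple[str, int, str, str, str, int], ...]:
    """Missense set-ups whose mutant codon offers an improvement target of
    the requested chemistry mode.

    Returns (ref_codon, codon_index, alt, novel_aa, novel_codon, n_edits)
    where the novel entry is the minimum-edit / lexicographically-first
    candidate for its amino acid — i.e. what the improvement algorithm picks
    when that amino acid carries the best site score.
    """
    out = []
    for ref, idx, alt in codon_setups(mismatch, "missense"):
        mut = ref[:idx] + alt + ref[idx + 1 :]
        mut_aa = GENETIC_CODE[mut]
        ref_aa = GENETIC_CODE[ref]
        seen: Set[str] = set()
        for ops, novel in enumerate_edits(mut):  # sorted by (n_edits, codon)
            aa = GENETIC_CODE[novel]
            if aa in (STOP, mut_aa, ref_aa) or aa in seen:
                continue
            seen.add(aa)
            if _mode_of(ops) == mode:
                out.append((ref, idx, alt, aa, novel, len(ops)))
    return tuple(out)


def _stop_escape(mut_codon: str) -> Tuple[str, int]:
    """Minimum-edit escape of a stop codon under A->G (always to TGG/Trp)."""
    best = None
    for ops, novel in enumerate_edits(mut_codon, {A_TO_G}):
        if GENETIC_CODE[novel] != STOP:
            best = (novel, len(ops))
            break  # enumerate_edits is sorted by (n_edits, codon)
    assert best is not None and best[0] == "TGG"
    return best


# --- allocation ---------------------------------------------------------------


def _largest_remainder(n: int, fractions: Mapping[str, float]) -> Dict[str, int]:
    shares = {k: n * f for k, f in fractions.items()}
    base = {k: int(math.floor(s)) for k, s in shares.items()}
    rem = n - sum(base.values())
    order = sorted(fractions, key=lambda k: (-(shares[k] - base[k]), k))
    for k in order[:rem]:
        base[k] += 1
    return base


# --- mutable sequence state ---------------------------------------------------


class _Seq:
    """A sequence under construction: characters plus plant bookkeeping."""

    __slots__ = ("chars", "immutable", "banned", "pair_guard")

    def __init__(self, seq: str):
        self.chars = list(seq)
        self.immutable: Set[int] = set()
        self.banned: Dict[int, Set[str]] = defaultdict(set)
        self.pair_guard: Set[int] = set()

    def __len__(self) -> int:
        return len(self.chars)

    def string(self) -> str:
        return "".join(self.chars)

    def plant(self, pos: int, base: str) -> None:
        self.chars[pos] = base
        self.immutable.add(pos)

    def allowed(self, pos: int, base: str) -> bool:
        if base in self.banned[pos]:
            return False
        if pos in self.pair_guard and base in "GC":
            left = self.chars[pos - 1] if pos > 0 else ""
            right = self.chars[pos + 1] if pos + 1 < len(self.chars) else ""
            if base in (left, right):
                return False
        return True

    def refill(self, pos: int, rng: np.random.Generator) -> bool:
        """Rewrite a mutable position with a different, constraint-respecting
        base; returns False (leaving the base) when none is available."""
        cands = [
            b for b in "ACGT" if b != self.chars[pos] and self.allowed(pos, b)
        ]
        if not cands:
            return False
        self.chars[pos] = cands[int(rng.integers(len(cands)))]
        return True


# --- manifest -----------------------------------------------------------------


@dataclass
class PlantedVariant:
    """Ground truth for one planted variant."""

    record_id: str
    region: str
    mismatch: str
    consequence: str
    category: str
    context_planted: bool = True
    adar_ok: Optional[bool] = None
    pam_distance: Optional[int] = None
    pam_in_range: Optional[bool] = None
    pam_side: Optional[str] = None
    rna_bystanders: Optional[int] = None
    rna_pathogenic: Optional[int] = None
    dna_bystanders: Optional[int] = None
    dna_pathogenic: Optional[int] = None
    offtarget_hits: Optional[int] = None
    offtarget_identities: List[float] = field(default_factory=list)
    improvable: Optional[bool] = None
    expected_novel_codon: Optional[str] = None
    expected_novel_aa: Optional[str] = None
    expected_n_edits: Optional[int] = None
    expected_mode: Optional[str] = None
    planted_delta: Optional[float] = None
    n_submitters: Optional[int] = None
    in_gnomad: Optional[bool] = None
    mit_score: Optional[float] = None
    mit_pass: Optional[bool] = None


@dataclass
class SyntheticTruth:
    """Manifest of every planted property; regeneration from the same seed
    is bit-identical."""

    seed: int
    variants: Dict[str, PlantedVariant] = field(default_factory=dict)
    cohort: Dict[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "cohort": self.cohort,
                "variants": {k: asdict(v) for k, v in self.variants.items()},
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, plus the truth manifest."""

    records: List[VariantRecord]
    distractors: List[VariantRecord]
    sequences: Dict[str, str]  # every context sequence (FASTA content)
    subject_ids: List[str]  # transcripts + decoys: the off-target subject set
    predictor: PredictorTable
    site_scores: Dict[str, Dict[str, float]]
    mit: Dict[str, float]
    freq: Dict[Tuple[str, int, str, str], float]
    expression: pd.DataFrame
    truth: SyntheticTruth

    @property
    def subjects(self) -> Dict[str, str]:
        return {sid: self.sequences[sid] for sid in self.subject_ids}


# --- transcriptome ------------------------------------------------------------


def gen_transcriptome(
    n_transcripts: int, length: int, seed: int
) -> Dict[str, str]:
    """Random CDS sequences: start ATG, end with a stop codon, no internal
    in-frame stops.  ``length`` must be >= 100 and divisible by 3."""
    if n_transcripts < 1:
        raise ValueError("need at least one transcript")
    if length < 100 or length % 3:
        raise ValueError("length must be >= 100 and divisible by 3")
    rng = _rng(seed, 1)
    sense = [c for c in SENSE_CODONS]
    n_mid = length // 3 - 2
    out = {}
    for t in range(n_transcripts):
        mid = rng.integers(0, len(sense), size=n_mid)
        codons = ["ATG"] + [sense[i] for i in mid] + [
            STOP_CODONS[int(rng.integers(3))]
        ]
        out[f"TX{t:05d}"] = "".join(codons)
    return out


# --- variant planting ---------------------------------------------------------


@dataclass
class _Plan:
    region: str
    mismatch: str
    consequence: str
    adar_ok: Optional[bool] = None
    pam: Optional[Tuple[str, int]] = None  # (side "down"/"up", distance)
    improv: Optional[Tuple[str, str]] = None  # ("missense", mode) | ("nonsense", "A_only")
    offtarget: Optional[Tuple[str, float]] = None  # ("hit"|"decoy", identity)


def _default_composition(n: int, p: Mapping[str, object]) -> List[_Plan]:
    n_coding = round(n * float(p["coding_fraction"]))
    n_nc = n - n_coding
    plans: List[_Plan] = []
    for region, n_region, mm_fracs, cons_fracs in (
        (CODING, n_coding, p["coding_mismatch"], p["coding_consequence"]),
        (GENE_NONCODING, n_nc, p["noncoding_mismatch"], p["noncoding_consequence"]),
    ):
        mm_counts = _largest_remainder(n_region, mm_fracs)  # type: ignore[arg-type]
        for mm in sorted(mm_counts):
            c = mm_counts[mm]
            if c == 0:
                continue
            cons_counts = _largest_remainder(c, cons_fracs)  # type: ignore[arg-type]
            if region == CODING:
                # feasibility shifts: consequences a mismatch type cannot
                # realise (and initiator/stop-lost on editable types, which
                # are kept mid-transcript) fall back to missense
                for cons in ("nonsense", "synonymous", "initiator_codon", "stop_lost"):
                    infeasible = not codon_setups(mm, cons)
                    off_slot = cons in ("initiator_codon", "stop_lost") and (
                        mm in DIRECT_TYPES + COMPLEMENTARY_TYPES
                    )
                    if cons_counts.get(cons) and (infeasible or off_slot):
                        cons_counts["missense"] = (
                            cons_counts.get("missense", 0) + cons_counts.pop(cons)
                        )
            for cons in sorted(cons_counts):
                plans.extend(
                    _Plan(region, mm, cons) for _ in range(cons_counts[cons])
                )
    return plans


def _assign_roles(plans: List[_Plan], p: Mapping[str, object], seed: int) -> None:
    rng = _rng(seed, 2)
    n = len(plans)

    def pick(indices: List[int], k: int) -> List[int]:
        idx = list(indices)
        rng.shuffle(idx)
        return idx[:k]

    # ADAR motif status for every G>A variant (planted fractions per region)
    for region in (CODING, GENE_NONCODING):
        ga = [
            i
            for i, pl in enumerate(plans)
            if pl.mismatch == "G>A" and pl.region == region
        ]
        n_ok = round(len(ga) * float(p["adar_ok"][region]))  # type: ignore[index]
        ok = set(pick(ga, n_ok))
        for i in ga:
            plans[i].adar_ok = i in ok

    # PAM presence among editable variants; in-range distances cycle 12..16,
    # decoys alternate 11/17, side alternates
    editable = [
        i
        for i, pl in enumerate(plans)
        if pl.mismatch in DIRECT_TYPES + COMPLEMENTARY_TYPES
    ]
    lo, hi = p["pam_distance_range"]  # type: ignore[misc]
    n_pam = round(len(editable) * float(p["pam_fraction"]))
    n_decoy = round(len(editable) * float(p["pam_decoy_fraction"]))
    chosen = pick(editable, n_pam + n_decoy)
    for k, i in enumerate(chosen[:n_pam]):
        plans[i].pam = ("down" if k % 2 else "up", lo + k % (hi - lo + 1))
    decoys = p["pam_decoy_distances"]  # type: ignore[assignment]
    for k, i in enumerate(chosen[n_pam:]):
        plans[i].pam = ("down" if k % 2 else "up", decoys[k % len(decoys)])

    # improvable plants live among the 8 non-editable mismatch types
    n_impr = round(n * float(p["improvable_fraction"]))
    split = _largest_remainder(n_impr, p["improvable_mode_split"])  # type: ignore[arg-type]
    n_nonsense = min(
        round(n_impr * float(p["improvable_nonsense_share"])), split["A_only"]
    )
    quotas = [
        ("nonsense", "A_only", n_nonsense),
        ("missense", "A_only", split["A_only"] - n_nonsense),
        ("missense", "C_only", split["C_only"]),
        ("missense", "combined", split["combined"]),
    ]
    for cons, mode, k in quotas:
        if k == 0:
            continue
        pool = [
            i
            for i, pl in enumerate(plans)
            if pl.region == CODING
            and pl.consequence == cons
            and pl.mismatch in OTHER_TYPES
            and pl.improv is None
            and (cons == "nonsense" or improvable_missense_setups(pl.mismatch, mode))
        ]
        if len(pool) < k:
            raise ValueError(
                f"composition infeasible: need {k} improvable {cons}/{mode} "
                f"slots, have {len(pool)}"
            )
        for i in pick(pool, k):
            plans[i].improv = (cons, mode)

    # off-target duplicates among the coding direct-editable (census) set
    census = [
        i
        for i, pl in enumerate(plans)
        if pl.region == CODING and pl.mismatch in DIRECT_TYPES
    ]
    n_hit = round(len(census) * float(p["offtarget_hit_fraction"]))
    n_ot_decoy = round(len(census) * float(p["offtarget_decoy_fraction"]))
    chosen = pick(census, n_hit + n_ot_decoy)
    cycle = p["offtarget_identity_cycle"]  # type: ignore[assignment]
    for k, i in enumerate(chosen[:n_hit]):
        plans[i].offtarget = ("hit", cycle[k % len(cycle)])
    for i in chosen[n_hit:]:
        plans[i].offtarget = ("decoy", 0.829)


def _pam_window(target: int, side: str, d: int, lo: int, hi: int) -> List[int]:
    if side == "down":
        j = target + d + 1
        return [q for q in range(j - hi - 1, j - lo) if q != target]
    q0 = target - d - 1
    return [q for q in range(q0 + lo + 1, q0 + hi + 2) if q != target]


def _plant_context(
    s: _Seq,
    target: int,
    plan: _Plan,
    entry: PlantedVariant,
    p: Mapping[str, object],
    rng: np.random.Generator,
) -> None:
    """Fill the +/-21 nt context zone around a planted target.

    Assumes the codon / target base and (for G>A) the ADAR neighbor are
    already planted.  Fills the bystander zone without the variant's
    editable base, keeps the PAM band free of GG/CC, plants the PAM and the
    bystander counts, and records final counts in the manifest entry.
    """
    b = EDITABLE_BASE.get(plan.mismatch)
    lo, hi = p["pam_distance_range"]  # type: ignore[misc]
    n = len(s)
    zone = [
        q for q in range(max(0, target - 10), min(n, target + 11)) if q != target
    ]
    # one left-to-right fill pass over the +/-21 region
    for q in range(max(0, target - 21), min(n, target + 22)):
        if b and abs(q - target) <= 10:
            s.banned[q].add(b)
        if abs(q - target) >= 9:
            s.pair_guard.add(q)
        if q not in s.immutable:
            s.refill(q, rng)

    if plan.pam is not None:
        side, d = plan.pam
        entry.pam_side, entry.pam_distance = side, d
        entry.pam_in_range = lo <= d <= hi
        if side == "down":
            j = target + d + 1  # N of NGG
            for q, base in ((j, "T"), (j + 1, "G"), (j + 2, "G"), (j + 3, "T")):
                if q < n:
                    s.plant(q, base)
        else:
            q0 = target - d - 1  # N of NGG, CCN on this strand
            for q, base in ((q0 - 3, "T"), (q0 - 2, "C"), (q0 - 1, "C"), (q0, "T")):
                if q >= 0:
                    s.plant(q, base)
    else:
        entry.pam_in_range = False

    if entry.pam_in_range and b:
        side, d = plan.pam  # type: ignore[misc]
        window = _pam_window(target, side, d, lo, hi)
        existing = sum(1 for q in window if s.chars[q] == b)
        mean = float(p["dna_bystander_mean"][plan.mismatch])  # type: ignore[index]
        want = int(rng.binomial(len(window), min(1.0, mean / len(window))))
        free = [q for q in window if q not in s.immutable]
        rng.shuffle(free)
        for q in free[: max(0, want - existing)]:
            s.plant(q, b)
        entry.dna_bystanders = sum(1 for q in window if s.chars[q] == b)

    if plan.mismatch in DIRECT_TYPES and b:
        window = (
            set(_pam_window(target, *plan.pam, lo, hi))
            if entry.pam_in_range and plan.pam
            else set()
        )
        existing = sum(1 for q in zone if s.chars[q] == b)
        want = int(rng.binomial(20, float(p["rna_bystander_p"][b])))  # type: ignore[index]
        free = [q for q in zone if q not in s.immutable and q not in window]
        rng.shuffle(free)
        for q in free[: max(0, want - existing)]:
            s.plant(q, b)
        entry.rna_bystanders = sum(1 for q in zone if s.chars[q] == b)


def gen_variants(
    transcriptome: Mapping[str, str],
    composition: Optional[Sequence[_Plan]] = None,
    contexts: Optional[Mapping[str, object]] = None,
    seed: int = 0,
) -> Tuple[SyntheticCohort, SyntheticTruth]:
    """Plant variants into a transcriptome; returns a partially-filled
    cohort (records + sequences + truth; tables come from :func:`gen_tables`).

    ``composition`` is a list of per-variant plans (defaulted from the
    cohort fractions in ``contexts``); each coding variant occupies its own
    transcript.  Raises when the transcriptome is too small for the
    composition.
    """
    p = dict(DEFAULTS)
    p.update(contexts or {})
    rng = _rng(seed, 3)
    if composition is None:
        raise ValueError("composition required; use generate_cohort for defaults")
    plans = list(composition)

    n_coding = sum(1 for pl in plans if pl.region == CODING)
    tx_ids = sorted(transcriptome)
    if n_coding > len(tx_ids):
        raise ValueError(
            f"composition infeasible: {n_coding} coding variants need "
            f"{n_coding} transcripts, transcriptome has {len(tx_ids)}"
        )

    seqs: Dict[str, _Seq] = {}
    records: List[VariantRecord] = []
    truth = SyntheticTruth(seed=seed)
    zones: List[dict] = []  # census query zones, for dedup + decoys
    tx_cursor = 0
    nc_len = int(p["noncoding_length"])

    for i, plan in enumerate(plans):
        rid = f"VAR{i:05d}"
        chrom = f"chr{(i % 22) + 1}"
        pos = 1_000_000 + i * 1_000
        entry = PlantedVariant(
            record_id=rid,
            region=plan.region,
            mismatch=plan.mismatch,
            consequence=plan.consequence,
            category=(
                "direct"
                if plan.mismatch in DIRECT_TYPES
                else "complementary"
                if plan.mismatch in COMPLEMENTARY_TYPES
                else "improvable"
                if plan.improv
                else "not_amendable"
            ),
            adar_ok=plan.adar_ok,
        )
        ref_base, alt = plan.mismatch.split(">")

        if plan.region == CODING:
            sid = tx_ids[tx_cursor]
            tx_cursor += 1
            s = seqs[sid] = _Seq(transcriptome[sid])
            setups = codon_setups(plan.mismatch, plan.consequence)
            # choose the codon set-up (improvable plants pin it; G>A plants
            # must respect the desired ADAR neighbor when it sits in-codon)
            if plan.improv and plan.consequence == "missense":
                cands = improvable_missense_setups(plan.mismatch, plan.improv[1])
                ref_codon, idx, alt2, novel_aa, novel_codon, n_edits = cands[
                    int(rng.integers(len(cands)))
                ]
                entry.improvable = True
                entry.expected_novel_codon = novel_codon
                entry.expected_novel_aa = novel_aa
                entry.expected_n_edits = n_edits
                entry.expected_mode = plan.improv[1]
            else:
                if plan.mismatch == "G>A" and plan.adar_ok is not None:
                    setups = tuple(
                        st
                        for st in setups
                        if st[1] == 0 or ((st[0][st[1] - 1] != "G") == plan.adar_ok)
                    )
                ref_codon, idx, alt2 = setups[int(rng.integers(len(setups)))]
                if plan.improv and plan.consequence == "nonsense":
                    mut = ref_codon[:idx] + alt + ref_codon[idx + 1 :]
                    novel_codon, n_edits = _stop_escape(mut)
                    entry.improvable = True
                    entry.expected_novel_codon = novel_codon
                    entry.expected_novel_aa = "W"
                    entry.expected_n_edits = n_edits
                    entry.expected_mode = "A_only"
                elif plan.consequence in ("missense", "nonsense"):
                    entry.improvable = False
            assert alt2 == alt
            if plan.consequence == "initiator_codon":
                slot = 0
            elif plan.consequence == "stop_lost":
                slot = len(s) // 3 - 1
            else:
                slot = _TARGET_CODON_SLOT
            start = slot * 3
            for k, base in enumerate(ref_codon):
                s.plant(start + k, base)
            target = start + idx
            mid_placed = plan.consequence not in ("initiator_codon", "stop_lost")
            if plan.mismatch == "G>A" and plan.adar_ok is not None and idx == 0:
                choices = ["C", "T"] if plan.adar_ok else ["G"]
                if target > 0:
                    s.plant(
                        target - 1, choices[int(rng.integers(len(choices)))]
                    )
            if mid_placed:
                _plant_context(s, target, plan, entry, p, rng)
            else:
                entry.context_planted = False
            rec = VariantRecord(
                record_id=rid,
                chrom=chrom,
                pos=pos,
                ref=ref_base,
                alt=alt,
                gene=f"GENE{tx_cursor - 1:05d}",
                transcript_id=sid,
                cds_offset=target + 1,
                region=CODING,
                consequence=plan.consequence,
                clin_sig="Pathogenic",
                strand="+",
            )
            if plan.region == CODING and plan.mismatch in DIRECT_TYPES and mid_placed:
                entry.offtarget_hits = 0
                zones.append(
                    {
                        "rid": rid,
                        "sid": sid,
                        "start": target - 20,
                        "end": target + 21,
                        "target": target,
                        "alt": alt,
                        "plan": plan,
                        "entry": entry,
                        "decoys": [],
                    }
                )
        else:
            sid = f"NC{i:05d}"
            base_seq = "".join(
                "ACGT"[k] for k in rng.integers(0, 4, size=nc_len)
            )
            s = seqs[sid] = _Seq(base_seq)
            target = _NC_TARGET
            s.plant(target, ref_base)
            if plan.mismatch == "G>A" and plan.adar_ok is not None:
                choices = ["C", "T"] if plan.adar_ok else ["G"]
                s.plant(target - 1, choices[int(rng.integers(len(choices)))])
            _plant_context(s, target, plan, entry, p, rng)
            rec = VariantRecord(
                record_id=rid,
                chrom=chrom,
                pos=pos,
                ref=ref_base,
                alt=alt,
                gene=f"GENE_{sid}",
                transcript_id=sid,
                cds_offset=None,
                region=GENE_NONCODING,
                consequence=plan.consequence,
                clin_sig="Pathogenic",
                strand="+",
                tx_pos=target,
            )
        records.append(rec)
        truth.variants[rid] = entry

    # planted off-target duplicates: one decoy transcript per duplicate
    decoy_seqs = _plant_offtarget_decoys(zones, seqs, rng)
    seqs.update(decoy_seqs)

    subject_ids = sorted(
        sid for sid in seqs if sid.startswith(("TX", "OT"))
    )
    _dedup_kmers(seqs, subject_ids, zones, int(p["seed_k"]), _rng(seed, 6))

    # finalize: freeze sequences, attach non-coding windows
    final = {sid: s.string() for sid, s in seqs.items()}
    for rec in records:
        if rec.region == GENE_NONCODING:
            seq = final[rec.transcript_id]
            t = rec.tx_pos
            start = max(0, t - 20)
            rec.window = seq[start : t + 21]
            rec.window_target = t - start

    cohort = SyntheticCohort(
        records=records,
        distractors=[],
        sequences=final,
        subject_ids=subject_ids,
        predictor=PredictorTable({}),
        site_scores={},
        mit={},
        freq={},
        expression=pd.DataFrame(),
        truth=truth,
    )
    return cohort, truth


def _plant_offtarget_decoys(
    zones: List[dict], seqs: Dict[str, _Seq], rng: np.random.Generator
) -> Dict[str, _Seq]:
    """Create one decoy transcript per planted duplicate.

    The 41-nt mutant query is copied into the decoy with a fixed mismatch
    pattern realising the planted identity; passing plants retain a >=13 nt
    exact run, the 0.829 decoy does not.
    """
    out: Dict[str, _Seq] = {}
    n_decoy = 0
    for z in zones:
        plan: _Plan = z["plan"]
        if plan.offtarget is None:
            continue
        kind, ident = plan.offtarget
        src = seqs[z["sid"]]
        segment = list(
            "".join(src.chars[z["start"] : z["end"]])
        )
        segment[z["target"] - z["start"]] = z["alt"]  # the mutant allele
        offsets = _MISMATCH_OFFSETS[ident]
        for off in offsets:
            orig = segment[off]
            cands = [b for b in "ACGT" if b != orig]
            segment[off] = cands[int(rng.integers(3))]
        sid = f"OT{n_decoy:04d}"
        n_decoy += 1
        flank1 = "".join("ACGT"[k] for k in rng.integers(0, 4, size=50))
        flank2 = "".join("ACGT"[k] for k in rng.integers(0, 4, size=50))
        s = _Seq(flank1 + "".join(segment) + flank2)
        for q in range(50, 50 + len(segment)):
            s.immutable.add(q)
        out[sid] = s
        z["decoys"].append(
            {"sid": sid, "seg_start": 50, "offsets": set(offsets)}
        )
        z["entry"].offtarget_identities.append(ident)
        if kind == "hit":
            z["entry"].offtarget_hits = z["entry"].offtarget_hits + 1
    return out


def _mutant_zone(seqs: Dict[str, _Seq], z: dict) -> str:
    chars = list("".join(seqs[z["sid"]].chars[z["start"] : z["end"]]))
    chars[z["target"] - z["start"]] = z["alt"]
    return "".join(chars)


def _dedup_kmers(
    seqs: Dict[str, _Seq],
    subject_ids: Sequence[str],
    zones: List[dict],
    k: int,
    rng: np.random.Generator,
    max_rounds: int = 12,
) -> None:
    """Rewrite filler until no unintended k-mer is shared between any census
    query window (mutant orientation, both strands) and any subject.

    Intended sharing — a query with its own source locus, or with its own
    planted decoy segments — is left alone.  Rewrites prefer the subject
    side; when the subject side is fully planted (another query's decoy
    segment), the query-side filler is rewritten instead, with the change
    propagated into that query's own decoy segments to preserve planted
    identities.
    """
    zone_by_rid = {z["rid"]: z for z in zones}

    def intended(z: dict, sid: str, pos: int) -> bool:
        if sid == z["sid"] and pos + k > z["start"] and pos < z["end"]:
            return True
        for d in z["decoys"]:
            if sid == d["sid"] and pos + k > d["seg_start"] and pos < d["seg_start"] + 41:
                return True
        return False

    def propagate(z: dict, zone_off: int) -> None:
        # a query-side filler change must be mirrored into this query's
        # planted duplicate segments (outside their mismatch offsets)
        src = seqs[z["sid"]]
        for d in z["decoys"]:
            if zone_off in d["offsets"]:
                continue
            seqs[d["sid"]].chars[d["seg_start"] + zone_off] = src.chars[
                z["start"] + zone_off
            ]

    for _ in range(max_rounds):
        index: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for sid in subject_ids:
            chars = seqs[sid].chars
            s = "".join(chars)
            for i in range(len(s) - k + 1):
                index[s[i : i + k]].append((sid, i))
        n_coll = 0
        for z in zones:
            zseq = _mutant_zone(seqs, z)
            oriented = [(zseq, False), (reverse_complement(zseq), True)]
            for qseq, is_rc in oriented:
                for o in range(len(qseq) - k + 1):
                    occs = index.get(qseq[o : o + k])
                    if not occs:
                        continue
                    fwd_off = (len(zseq) - o - k) if is_rc else o
                    for sid, i in occs:
                        if intended(z, sid, i):
                            continue
                        n_coll += 1
                        subj = seqs[sid]
                        mut = [
                            q for q in range(i, i + k) if q not in subj.immutable
                        ]
                        rng.shuffle(mut)
                        changed = False
                        for q in mut:
                            if subj.refill(q, rng):
                                owner = next(
                                    (
                                        zz
                                        for zz in zones
                                        if zz["sid"] == sid
                                        and zz["start"] <= q < zz["end"]
                                    ),
                                    None,
                                )
                                if owner is not None:
                                    propagate(owner, q - owner["start"])
                                changed = True
                                break
                        if not changed:
                            src = seqs[z["sid"]]
                            cands = [
                                off
                                for off in range(fwd_off, fwd_off + k)
                                if (z["start"] + off) not in src.immutable
                                and off != (z["target"] - z["start"])
                            ]
                            rng.shuffle(cands)
                            for off in cands:
                                if src.refill(z["start"] + off, rng):
                                    propagate(z, off)
                                    break
        if n_coll == 0:
            return
    # verify convergence
    index = defaultdict(list)
    for sid in subject_ids:
        s = seqs[sid].string()
        for i in range(len(s) - k + 1):
            index[s[i : i + k]].append((sid, i))
    for z in zones:
        zseq = _mutant_zone(seqs, z)
        for qseq, is_rc in ((zseq, False), (reverse_complement(zseq), True)):
            for o in range(len(qseq) - k + 1):
                for sid, i in index.get(qseq[o : o + k], ()):
                    if not intended(z, sid, i):
                        raise AssertionError(
                            f"k-mer dedup did not converge: {z['rid']} vs {sid}:{i}"
                        )


# --- tables -------------------------------------------------------------------


def gen_tables(
    cohort: SyntheticCohort,
    contexts: Optional[Mapping[str, object]] = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Fill in predictor / site-score / MIT / frequency / expression tables
    plus distractor records, all consistent with the manifest."""
    p = dict(DEFAULTS)
    p.update(contexts or {})
    rng = _rng(seed, 5)
    truth = cohort.truth
    records = cohort.records
    by_id = {r.record_id: r for r in records}

    # predictor table over every bystander position of coding variants
    lo, hi = p["pam_distance_range"]  # type: ignore[misc]
    entries: Dict[Tuple[str, int, str], Tuple[float, str]] = {}
    for rid, ent in truth.variants.items():
        rec = by_id[rid]
        if rec.region != CODING or not ent.context_planted:
            continue
        b = EDITABLE_BASE.get(ent.mismatch)
        if not b:
            continue
        seq = cohort.sequences[rec.transcript_id]
        target = rec.cds_offset - 1  # type: ignore[operator]
        zone = [
            q
            for q in range(max(0, target - 10), min(len(seq), target + 11))
            if q != target and seq[q] == b
        ]
        window: List[int] = []
        if ent.pam_in_range and ent.pam_side:
            window = [
                q
                for q in _pam_window(target, ent.pam_side, ent.pam_distance, lo, hi)
                if seq[q] == b
            ]
        p_path = float(p["pathogenic_fraction"][ent.mismatch])  # type: ignore[index]
        alt = IMPLIED_ALT[b]
        classes = {}
        for q in sorted(set(zone) | set(window)):
            is_path = bool(rng.random() < p_path)
            classes[q] = is_path
            score = (
                float(rng.uniform(0.7, 1.0))
                if is_path
                else float(rng.uniform(0.0, 0.3))
            )
            entries[(rec.transcript_id, q + 1, alt)] = (
                score,
                "likely_pathogenic" if is_path else "likely_benign",
            )
        if ent.rna_bystanders is not None:
            ent.rna_pathogenic = sum(1 for q in zone if classes[q])
        if ent.dna_bystanders is not None:
            ent.dna_pathogenic = sum(1 for q in window if classes[q])
    # non-coding bystanders have no predictor coverage: misses count as
    # not pathogenic, so the planted truth is zero
    for ent in truth.variants.values():
        if ent.rna_bystanders is not None and ent.rna_pathogenic is None:
            ent.rna_pathogenic = 0
        if ent.dna_bystanders is not None and ent.dna_pathogenic is None:
            ent.dna_pathogenic = 0
    cohort.predictor = PredictorTable(entries)

    # SIFT-style site scores: planted improvables get a strictly-improving
    # novel amino acid; other candidates get only sub-floor / absent entries
    d_lo, d_hi = p["delta_range"]  # type: ignore[misc]
    for rid, ent in truth.variants.items():
        rec = by_id[rid]
        if rec.region != CODING or rec.consequence not in ("missense", "nonsense"):
            continue
        if rec.mismatch in DIRECT_TYPES + COMPLEMENTARY_TYPES:
            continue  # direct variants are reverted; complementary left uncovered
        scores: Dict[str, float] = {}
        setup = _record_codons(rec, cohort.sequences)
        if setup is None:
            continue
        ref_codon, mut_codon = setup
        mut_aa = GENETIC_CODE[mut_codon]
        reachable = sorted(
            {
                GENETIC_CODE[nov]
                for _ops, nov in enumerate_edits(mut_codon)
                if GENETIC_CODE[nov] != STOP
            }
        )
        if ent.improvable:
            delta_raw = float(rng.uniform(d_lo, d_hi))
            if mut_aa == STOP:
                novel_r = round(delta_raw, 4)
                scores["W"] = novel_r
                ent.planted_delta = novel_r  # stop baseline is 0
            else:
                base_r = round(float(rng.uniform(0.0, 0.04)), 4)
                novel_r = round(base_r + delta_raw, 4)
                scores[mut_aa] = base_r
                scores[ent.expected_novel_aa] = novel_r
                ent.planted_delta = novel_r - base_r
                for aa in reachable:
                    if aa not in scores:
                        scores[aa] = round(float(rng.uniform(0.0, 0.049)), 4)
        else:
            if mut_aa == STOP:
                pass  # no Trp coverage: the stop cannot be scored, no result
            else:
                scores[mut_aa] = round(float(rng.uniform(0.0, 0.04)), 4)
                for aa in reachable:
                    if aa != mut_aa:
                        scores[aa] = round(float(rng.uniform(0.0, 0.049)), 4)
        if scores:
            cohort.site_scores[rid] = scores

    # MIT specificity among in-range-PAM variants: planted pass/fail counts
    pam_ids = [
        rid for rid, ent in truth.variants.items() if ent.pam_in_range
    ]
    n_pass = round(len(pam_ids) * float(p["mit_pass_fraction"]))
    order = list(pam_ids)
    rng.shuffle(order)
    for k, rid in enumerate(order):
        ok = k < n_pass
        score = float(rng.uniform(51.0, 100.0) if ok else rng.uniform(0.0, 50.0))
        cohort.mit[rid] = round(score, 2)
        truth.variants[rid].mit_score = round(score, 2)
        truth.variants[rid].mit_pass = ok

    # submitters and gnomAD presence
    ids = [r.record_id for r in records]
    n_high = round(len(ids) * float(p["submitter_high_fraction"]))
    order = list(ids)
    rng.shuffle(order)
    for k, rid in enumerate(order):
        high = k < n_high
        n_sub = int(rng.integers(3, 16)) if high else int(rng.integers(1, 3))
        by_id[rid].n_submitters = n_sub
        truth.variants[rid].n_submitters = n_sub
    n_gnomad = round(len(ids) * float(p["gnomad_presence_fraction"]))
    rng.shuffle(order)
    for k, rid in enumerate(order):
        present = k < n_gnomad
        truth.variants[rid].in_gnomad = present
        if present:
            r = by_id[rid]
            cohort.freq[(r.chrom, r.pos, r.ref, r.alt)] = float(
                10 ** rng.uniform(-5, -2)
            )

    # clinically "conflicting" significance strings for a planted subset
    n_conf = round(len(ids) * float(p["conflict_kept_fraction"]))
    rng.shuffle(order)
    for rid in order[:n_conf]:
        by_id[rid].clin_sig = "Conflicting interpretations of pathogenicity"
        by_id[rid].submitter_sigs = ["Benign", "Pathogenic"]

    # expression matrix over the coding genes
    tissues = list(p["tissues"])  # type: ignore[arg-type]
    genes = sorted({r.gene for r in records if r.region == CODING})
    n_liver = int(p["n_liver_specific"])
    n_brain = int(p["n_brain_specific"])
    n_decoy = int(p["n_expression_decoys"])
    liver_genes = genes[:n_liver]
    brain_genes = genes[n_liver : n_liver + n_brain]
    decoy_genes = genes[n_liver + n_brain : n_liver + n_brain + n_decoy]
    rows = []
    for g in genes:
        if g in liver_genes:
            row = {t: float(rng.uniform(0.0, 5.0)) for t in tissues}
            row["liver"] = float(rng.uniform(15.0, 100.0))
        elif g in brain_genes:
            row = {t: float(rng.uniform(0.0, 5.0)) for t in tissues}
            row["brain"] = float(rng.uniform(15.0, 100.0))
        elif g in decoy_genes:
            # highly-but-not-specifically expressed: rejected by the filter
            row = {t: float(rng.uniform(10.5, 13.0)) for t in tissues}
        else:
            row = {t: float(rng.uniform(0.0, 8.0)) for t in tissues}
        row["gene"] = g
        rows.append(row)
    cohort.expression = pd.DataFrame(rows).set_index("gene")[tissues]
    truth.cohort["liver_genes"] = liver_genes
    truth.cohort["brain_genes"] = brain_genes

    cohort.distractors = _gen_distractors(p, _rng(seed, 7))
    _cohort_summary(cohort, p)
    return cohort


def _record_codons(
    rec: VariantRecord, sequences: Mapping[str, str]
) -> Optional[Tuple[str, str]]:
    if rec.cds_offset is None:
        return None
    seq = sequences[rec.transcript_id]
    pos0 = rec.cds_offset - 1
    start = (pos0 // 3) * 3
    ref_codon = seq[start : start + 3]
    if len(ref_codon) != 3:
        return None
    idx = pos0 - start
    mut_codon = ref_codon[:idx] + rec.alt + ref_codon[idx + 1 :]
    return ref_codon, mut_codon


def _gen_distractors(
    p: Mapping[str, object], rng: np.random.Generator
) -> List[VariantRecord]:
    """Rows the filtering cascade must remove, with known per-rule counts."""
    out: List[VariantRecord] = []
    k = int(p["n_exclusion_distractors"])
    i = 0

    def add(**kw) -> None:
        nonlocal i
        base = dict(
            record_id=f"DIS{i:05d}",
            chrom=f"chr{(i % 22) + 1}",
            pos=5_000_000 + i,
            ref="G",
            alt="A",
            gene="GENEX",
            region=GENE_NONCODING,
            consequence="intron",
            clin_sig="Pathogenic",
        )
        base.update(kw)
        out.append(VariantRecord(**base))
        i += 1

    for _ in range(k):
        add(consequence="downstream")
    for _ in range(k):
        add(consequence="upstream")
    for _ in range(k):
        add(ref="A", alt="A")
    for _ in range(k):
        add(consequence=None)
    for _ in range(k):
        add(ref="AT")
    for _ in range(k):
        add(chrom="chrM")
    n_benign = int(p["n_benign_distractors"])
    sigs = ("Benign", "Likely benign", "Uncertain significance")
    for j in range(n_benign):
        add(clin_sig=sigs[j % 3])
    for _ in range(int(p["n_conflict_dropped"])):
        add(
            clin_sig="Conflicting interpretations of pathogenicity",
            submitter_sigs=["Benign", "Uncertain significance"],
        )
    return out


def _cohort_summary(cohort: SyntheticCohort, p: Mapping[str, object]) -> None:
    truth = cohort.truth
    ents = list(truth.variants.values())
    n = len(ents)
    cats = {c: sum(1 for e in ents if e.category == c) for c in
            ("direct", "complementary", "improvable", "not_amendable")}
    ga_c = [e for e in ents if e.mismatch == "G>A" and e.region == CODING]
    ga_nc = [e for e in ents if e.mismatch == "G>A" and e.region == GENE_NONCODING]
    editable = [e for e in ents if e.mismatch in DIRECT_TYPES + COMPLEMENTARY_TYPES]
    census = [e for e in ents if e.offtarget_hits is not None]
    mit = [e for e in ents if e.mit_pass is not None]
    deltas = [e.planted_delta for e in ents if e.planted_delta is not None]
    truth.cohort.update(
        {
            "n_variants": n,
            "n_distractors": len(cohort.distractors),
            "category_counts": cats,
            "fraction_direct": cats["direct"] / n,
            "fraction_complementary": cats["complementary"] / n,
            "fraction_improvable": cats["improvable"] / n,
            "adar_ok_fraction_coding": (
                sum(1 for e in ga_c if e.adar_ok) / len(ga_c) if ga_c else None
            ),
            "adar_ok_fraction_noncoding": (
                sum(1 for e in ga_nc if e.adar_ok) / len(ga_nc) if ga_nc else None
            ),
            "pam_fraction": (
                sum(1 for e in editable if e.pam_in_range) / len(editable)
                if editable
                else None
            ),
            "zero_offtarget_fraction": (
                sum(1 for e in census if e.offtarget_hits == 0) / len(census)
                if census
                else None
            ),
            "mit_pass_fraction": (
                sum(1 for e in mit if e.mit_pass) / len(mit) if mit else None
            ),
            "mean_planted_delta": float(np.mean(deltas)) if deltas else None,
        }
    )


# --- top-level convenience ----------------------------------------------------


def generate_cohort(
    n_variants: int = 2000,
    seed: int = 0,
    contexts: Optional[Mapping[str, object]] = None,
) -> SyntheticCohort:
    """Generate a complete seeded cohort with default study conditions."""
    p = dict(DEFAULTS)
    p.update(contexts or {})
    p["n_benign_distractors"] = round(
        n_variants * float(p["benign_distractor_fraction"])
    )
    plans = _default_composition(n_variants, p)
    _assign_roles(plans, p, seed)
    n_coding = sum(1 for pl in plans if pl.region == CODING)
    transcriptome = gen_transcriptome(
        max(1, n_coding), int(p["transcript_length"]), seed
    )
    cohort, _truth = gen_variants(transcriptome, plans, p, seed)
    return gen_tables(cohort, p, seed)


# --- file emission ------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, outdir: str) -> Dict[str, str]:
    """Emit the cohort in the dialects the pipeline reads; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(p("transcripts.fa"), "w") as fh:
        for sid in sorted(cohort.sequences):
            fh.write(f">{sid}\n{cohort.sequences[sid]}\n")
    from .variant_io import to_tsv

    to_tsv(cohort.records + cohort.distractors, p("variants.tsv"))
    _write_vcf(cohort, p("clinvar.vcf"))
    cohort.predictor.to_tsv(p("predictor.tsv"))
    pd.DataFrame(
        [
            {"record_id": rid, "amino_acid": aa, "score": s}
            for rid, scores in sorted(cohort.site_scores.items())
            for aa, s in sorted(scores.items())
        ]
    ).to_csv(p("site_scores.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [{"record_id": rid, "mit_score": s} for rid, s in sorted(cohort.mit.items())]
    ).to_csv(p("mit.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"chrom": c, "pos": pos, "ref": r, "alt": a, "af": af}
            for (c, pos, r, a), af in sorted(cohort.freq.items())
        ]
    ).to_csv(p("frequency.tsv"), sep="\t", index=False)
    cohort.expression.to_csv(p("expression.tsv"), sep="\t")
    with open(p("manifest.json"), "w") as fh:
        fh.write(cohort.truth.to_json())
    return paths


def read_cohort(indir: str) -> SyntheticCohort:
    """Read a cohort back from the files :func:`write_cohort` emitted."""
    import os

    from .variant_io import parse_variant_table, read_fasta

    def p(name: str) -> str:
        return os.path.join(indir, name)

    sequences = read_fasta(p("transcripts.fa"))
    all_records = parse_variant_table(p("variants.tsv"), dialect="internal")
    records = [r for r in all_records if r.record_id.startswith("VAR")]
    distractors = [r for r in all_records if not r.record_id.startswith("VAR")]
    predictor = (
        PredictorTable.from_tsv(p("predictor.tsv"))
        if os.path.exists(p("predictor.tsv"))
        else PredictorTable({})
    )
    site_scores: Dict[str, Dict[str, float]] = {}
    if os.path.exists(p("site_scores.tsv")):
        df = pd.read_csv(p("site_scores.tsv"), sep="\t")
        for row in df.itertuples():
            site_scores.setdefault(str(row.record_id), {})[
                str(row.amino_acid)
            ] = float(row.score)
    mit: Dict[str, float] = {}
    if os.path.exists(p("mit.tsv")):
        df = pd.read_csv(p("mit.tsv"), sep="\t")
        mit = {str(r.record_id): float(r.mit_score) for r in df.itertuples()}
    freq: Dict[Tuple[str, int, str, str], float] = {}
    if os.path.exists(p("frequency.tsv")):
        df = pd.read_csv(p("frequency.tsv"), sep="\t")
        freq = {
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): float(r.af)
            for r in df.itertuples()
        }
    expression = pd.DataFrame()
    if os.path.exists(p("expression.tsv")):
        expression = pd.read_csv(p("expression.tsv"), sep="\t", index_col=0)
    truth = SyntheticTruth(seed=-1)
    if os.path.exists(p("manifest.json")):
        with open(p("manifest.json")) as fh:
            raw = json.load(fh)
        truth = SyntheticTruth(
            seed=raw["seed"],
            variants={
                k: PlantedVariant(**v) for k, v in raw["variants"].items()
            },
            cohort=raw["cohort"],
        )
    return SyntheticCohort(
        records=records,
        distractors=distractors,
        sequences=sequences,
        subject_ids=sorted(s for s in sequences if s.startswith(("TX", "OT"))),
        predictor=predictor,
        site_scores=site_scores,
        mit=mit,
        freq=freq,
        expression=expression,
        truth=truth,
    )


def _write_vcf(cohort: SyntheticCohort, path: str) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">',
        '##INFO=<ID=CLNSIGCONF,Number=.,Type=String,Description="Per-submitter significance">',
        '##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene">',
    ]
    contigs = sorted(
        {r.chrom for r in cohort.records + cohort.distractors},
        key=lambda c: (len(c), c),
    )
    lines.extend(f"##contig=<ID={c}>" for c in contigs)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(
        cohort.records + cohort.distractors, key=lambda r: (r.chrom, r.pos)
    ):
        if not r.is_snv():
            continue  # VCF route carries well-formed SNVs only
        info = [f"CLNSIG={r.clin_sig.replace(' ', '_')}"]
        if r.submitter_sigs:
            conf = "|".join(s.replace(" ", "_") for s in r.submitter_sigs)
            info.append(f"CLNSIGCONF={conf}")
        if r.gene:
            info.append(f"GENEINFO={r.gene}:0")
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.record_id}\t{r.ref}\t{r.alt}\t.\t.\t"
            + ";".join(info)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
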