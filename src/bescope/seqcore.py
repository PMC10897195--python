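"""Genetic-code primitives for base-editing analysis.

Deaminase base editors can only perform two chemistries on the coding
(mRNA-sense) strand: adenosine deamination reads as an A->G change, and
cytidine deamination as a C->T change (U is represented as T throughout,
since all sequence handling is in DNA alphabet).  Everything downstream —
editability calls, bystander enumeration and the codon-improvement
algorithm — reduces to enumerating subsets of A->G / C->T edits within a
codon and scoring the translated products.

This module provides the codon table, edit-subset enumeration, and the
BLOSUM62 substitution matrix extended with an explicit stop-codon policy.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, product
from typing import Dict, FrozenSet, Iterable, List, Set, Tuple

from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

BASES = "ACGT"
STOP = "*"
#: one-letter codes of the 20 standard amino acids
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: the closed 21-symbol alphabet used by scorers
AA_ALPHABET = frozenset(AMINO_ACIDS) | {STOP}

#: the two deaminase chemistries, as (from_base, to_base) pairs
A_TO_G: Tuple[str, str] = ("A", "G")
C_TO_T: Tuple[str, str] = ("C", "T")
ALL_CHEMISTRIES: FrozenSet[Tuple[str, str]] = frozenset({A_TO_G, C_TO_T})

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: standard genetic code, all 64 codons -> one-letter amino acid or ``*``
GENETIC_CODE: Dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    GENETIC_CODE[_stop] = STOP

ALL_CODONS: Tuple[str, ...] = tuple(sorted(GENETIC_CODE))  # lexicographic ACGT
SENSE_CODONS: Tuple[str, ...] = tuple(c for c in ALL_CODONS if GENETIC_CODE[c] != STOP)
STOP_CODONS: Tuple[str, ...] = tuple(_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class InvalidAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def _check_nt(seq: str) -> str:
    s = seq.upper()
    if any(b not in "ACGT" for b in s):
        raise InvalidAlphabetError(f"non-ACGT character in {seq!r}")
    return s


def translate(codon: str) -> str:
    """Translate a single codon under the standard genetic code.

    Returns a one-letter amino-acid code; the three stop codons
    (TAA/TAG/TGA) map to :data:`STOP` (``*``).
    """
    c = _check_nt(codon)
    if len(c) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return GENETIC_CODE[c]


def complement(base: str) -> str:
    return _check_nt(base).translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    return _check_nt(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class EditOp:
    """A single deaminase edit inside a codon.

    position is the 0-based codon index (0-2); the only legal
    (from_base, to_base) pairs are (A, G) and (C, T).
    """

    position: int
    from_base: str
    to_base: str

    def __post_init__(self) -> None:
        if (self.from_base, self.to_base) not in (A_TO_G, C_TO_T):
            raise ValueError(
                f"illegal chemistry {self.from_base}->{self.to_base}; "
                "deaminases only perform A->G and C->T"
            )
        if not 0 <= self.position <= 2:
            raise ValueError(f"codon position out of range: {self.position}")


def _normalize_chemistries(
    chemistries: Iterable[Tuple[str, str]]
) -> FrozenSet[Tuple[str, str]]:
    chems = frozenset(chemistries)
    if not chems:
        raise ValueError("chemistries must be nonempty")
    if not chems <= ALL_CHEMISTRIES:
        raise ValueError(f"unknown chemistries: {chems - ALL_CHEMISTRIES}")
    return chems


def enumerate_edits(
    codon: str,
    chemistries: Iterable[Tuple[str, str]] = ALL_CHEMISTRIES,
) -> List[Tuple[FrozenSet[EditOp], str]]:
    """Enumerate every nonempty edit subset of a codon.

    For each position holding an editable base (A when A->G is allowed, C
    when C->T is allowed) the deaminase may or may not act, so a codon with
    k editable positions yields 2**k - 1 distinct (edit set, novel codon)
    entries.  The novel codon always differs from the input.
    """
    c = _check_nt(codon)
    if len(c) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    chems = _normalize_chemistries(chemistries)
    targets = {frm: to for frm, to in chems}
    editable = [i for i, b in enumerate(c) if b in targets]
    out: List[Tuple[FrozenSet[EditOp], str]] = []
    for r in range(1, len(editable) + 1):
        for subset in combinations(editable, r):
            novel = list(c)
            ops = []
            for i in subset:
                ops.append(EditOp(i, c[i], targets[c[i]]))
                novel[i] = targets[c[i]]
            out.append((frozenset(ops), "".join(novel)))
    out.sort(key=lambda e: (len(e[0]), e[1]))
    return out


# --- substitution scoring ---------------------------------------------------

#: sentinel score for retaining a stop codon (stop vs stop); effectively -inf
STOP_RETAIN_SCORE = -1_000_000
#: sentinel score for any pair with exactly one STOP member.  Ranks above
#: STOP_RETAIN_SCORE and below every real BLOSUM entry, so escaping a stop
#: codon to any amino acid is always an improvement over keeping the stop.
STOP_ESCAPE_SCORE = -999_999


class SubstitutionMatrix:
    """Symmetric amino-acid substitution scores with a stop policy.

    Scores between the 20 standard residues come from the wrapped matrix
    (BLOSUM62 by default, entries −4…11).  Pairs involving the STOP symbol
    are resolved by sentinels: STOP↔STOP is :data:`STOP_RETAIN_SCORE` and a
    single-STOP pair is :data:`STOP_ESCAPE_SCORE`, guaranteeing that any
    substitution of a stop codon by a real amino acid ranks above retaining
    the stop.  Sentinels never mix with real BLOSUM arithmetic: callers
    compare scores, they do not sum them.
    """

    def __init__(self, scores: Dict[Tuple[str, str], int], name: str = "custom"):
        self.name = name
        self._scores = dict(scores)
        for (a, b), v in scores.items():
            if self._scores.get((b, a), v) != v:
                raise ValueError(f"asymmetric scores for pair {a},{b}")
            self._scores[(b, a)] = v

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        raw = substitution_matrices.load("BLOSUM62")
        scores = {
            (a, b): int(raw[a][b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
        }
        return cls(scores, name="BLOSUM62")

    def score(self, a: str, b: str) -> int:
        if a not in AA_ALPHABET or b not in AA_ALPHABET:
            raise KeyError(f"unknown amino-acid symbol in pair ({a!r}, {b!r})")
        if a == STOP and b == STOP:
            return STOP_RETAIN_SCORE
        if a == STOP or b == STOP:
            return STOP_ESCAPE_SCORE
        return self._scores[(a, b)]

    @property
    def min_score(self) -> int:
        return min(self._scores.values())

    @property
    def max_score(self) -> int:
        return max(self._scores.values())


@lru_cache(maxsize=1)
def blosum62() -> SubstitutionMatrix:
    """The embedded BLOSUM62 matrix (cached)."""
    return SubstitutionMatrix.blosum62()


def matrix_score(matrix: SubstitutionMatrix, a: str, b: str) -> int:
    """Symmetric substitution score, with STOP pairs resolved by the policy."""
    return matrix.score(a, b)


def substitution_map(
    chemistries: Iterable[Tuple[str, str]] = ALL_CHEMISTRIES,
) -> Dict[str, Set[str]]:
    """All amino-acid substitutions reachable by codon editing.

    For every codon, every nonempty edit subset under the given chemistries
    is applied and the novel codon translated; results are aggregated per
    source amino acid (STOP included as a source and, where reachable, as a
    target).  Identity outcomes (novel amino acid equal to the source,
    i.e. synonymous edits or stop-to-stop) are omitted.
    """
    chems = _normalize_chemistries(chemistries)
    out: Dict[str, Set[str]] = {}
    for codon in ALL_CODONS:
        src = GENETIC_CODE[codon]
        out.setdefault(src, set())
        for _ops, novel in enumerate_edits(codon, chems):
            if GENETIC_CODE[novel] != src:
                out[src].add(GENETIC_CODE[novel])
    return out
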