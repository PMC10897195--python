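"""Per-variant base-editing options.

Only two of the twelve SNV mismatch types can be reverted by pointing a
deaminase at the mutant base itself ("direct" editing): G>A (the mutant A is
deaminated back to G) and T>C (the mutant C back to T/U).  At the DNA level
the complementary strand is also available, which extends correction to the
two reciprocal types C>T and A>G ("complementary" editing).  The remaining
eight types cannot be corrected; missense and nonsense variants among them
are candidates for the codon-improvement algorithm instead.

RNA editors acting on mature mRNA in the cytoplasm only reach exonic
positions; nuclear RNA editors (e.g. ADAR p110 recruitment) also reach
intronic/UTR positions of the pre-mRNA, and DNA editors reach any position
in a gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

from .variant_io import CODING, GENE_NONCODING, VariantRecord

#: all 12 ordered mismatch types
MISMATCH_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

DIRECT_TYPES = ("G>A", "T>C")
COMPLEMENTARY_TYPES = ("C>T", "A>G")

A_TO_I = "A_to_I"
C_TO_U = "C_to_U"


@dataclass
class EditabilityCall:
    """Editing options for one variant.

    Invariants: cytoplasmic RNA editing implies nuclear RNA editing implies
    direct DNA editing; direct and complementary DNA editing are mutually
    exclusive; a variant is an improvement candidate iff it has no direct
    option and is missense or nonsense.
    """

    record_id: str
    rna_direct_cytoplasmic: bool = False
    rna_direct_nuclear: bool = False
    dna_direct: bool = False
    dna_complementary: bool = False
    chemistry: str = "none"
    improvement_candidate: bool = False

    def validate(self) -> None:
        if self.rna_direct_cytoplasmic and not self.rna_direct_nuclear:
            raise AssertionError("cytoplasmic RNA call without nuclear call")
        if self.rna_direct_nuclear and not self.dna_direct:
            raise AssertionError("nuclear RNA call without DNA direct call")
        if self.dna_direct and self.dna_complementary:
            raise AssertionError("direct and complementary calls are exclusive")

    @property
    def category(self) -> str:
        """Primary reporting category (direct > complementary > improvement)."""
        if self.dna_direct:
            return "direct"
        if self.dna_complementary:
            return "complementary"
        if self.improvement_candidate:
            return "improvable"
        return "not_amendable"


def call_editability(record: VariantRecord) -> EditabilityCall:
    """Classify one variant's base-editing options.

    The mismatch type is evaluated in transcript orientation (the strand the
    editor's guide pairs with).  Intergenic records fall outside the
    gene-scoped analysis and receive no flags.
    """
    call = EditabilityCall(record_id=record.record_id)
    in_gene = record.region in (CODING, GENE_NONCODING)
    if not in_gene:
        return call
    mm = record.mismatch_tx
    if mm in DIRECT_TYPES:
        call.dna_direct = True
        call.rna_direct_nuclear = True
        call.rna_direct_cytoplasmic = record.region == CODING
        call.chemistry = A_TO_I if mm == "G>A" else C_TO_U
    elif mm in COMPLEMENTARY_TYPES:
        call.dna_complementary = True
        # the deamination happens on the opposite strand
        call.chemistry = A_TO_I if mm == "C>T" else C_TO_U
    if not call.dna_direct and record.consequence in ("missense", "nonsense"):
        call.improvement_candidate = True
    call.validate()
    return call


def mismatch_census(
    records: Sequence[VariantRecord], orientation: str = "genomic"
) -> Dict[str, int]:
    """Exhaustive partition of records over the 12 mismatch types.

    ``orientation`` selects genomic (plus-strand, as reported by ClinVar)
    or transcript-oriented mismatch types.
    """
    if orientation not in ("genomic", "transcript"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    census = {mm: 0 for mm in MISMATCH_TYPES}
    for r in records:
        mm = r.mismatch if orientation == "genomic" else r.mismatch_tx
        census[mm] += 1
    assert sum(census.values()) == len(records)
    return census
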