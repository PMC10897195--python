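"""Variant-table parsing, the pathogenicity filtering cascade, and CDS context.

Input dialects:

* ``internal`` — the package's own annotated TSV (written by :func:`to_tsv`),
  round-trip safe.
* ``ucsc_tsv`` — a UCSC-track-style TSV/BED hybrid with a configurable column
  map; BED half-open 0-based starts are converted to 1-based positions.
* ``vcf`` — a ClinVar-style VCF; clinical significance is read from CLNSIG and
  per-submitter significances from CLNSIGCONF.

The filtering cascade mirrors a ClinVar curation workflow: structural /
annotation exclusions first (upstream/downstream transcript variants, rows
with no sequence alteration, rows with no molecular consequence, rows
misclassified as SNVs, mitochondrial rows), then the pathogenicity phrase
rule (any significance string containing "pathogenic", case-insensitive,
with "conflicting interpretations" resolved through per-submitter reports),
and finally a consistency check of the stored reference allele against the
transcript CDS.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .seqcore import complement, reverse_complement

logger = logging.getLogger(__name__)

CODING = "coding"
GENE_NONCODING = "gene_noncoding"
INTERGENIC = "intergenic"

CONSEQUENCES = (
    "missense",
    "nonsense",
    "synonymous",
    "initiator_codon",
    "stop_lost",
    "splice",
    "intron",
    "UTR",
    "upstream",
    "downstream",
    "other",
)

MITO_CHROMS = {"chrM", "MT", "chrMT", "M"}


@dataclass
class VariantRecord:
    """One single-nucleotide variant with its gene/transcript context.

    ``ref``/``alt`` are plus-strand (genomic) alleles; transcript-oriented
    alleles are derived via :attr:`strand`.  ``cds_offset`` is 1-based within
    the CDS.  ``window``/``window_target`` hold the +/-20 nt transcript-sense
    reference context once attached (or provided by a generator for
    non-coding records).
    """

    record_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    transcript_id: str = ""
    cds_offset: Optional[int] = None
    region: str = INTERGENIC
    consequence: Optional[str] = None
    clin_sig: str = ""
    submitter_sigs: Optional[List[str]] = None
    n_submitters: Optional[int] = None
    strand: str = "+"
    # attached context
    tx_pos: Optional[int] = None  # 0-based position in the context sequence
    codon: Optional[str] = None
    codon_index: Optional[int] = None
    window: Optional[str] = None
    window_target: Optional[int] = None

    @property
    def mismatch(self) -> str:
        """Genomic (plus-strand) mismatch type, e.g. ``"G>A"``."""
        return f"{self.ref}>{self.alt}"

    @property
    def mismatch_tx(self) -> str:
        """Transcript-oriented mismatch type (complemented on − strand)."""
        if self.strand == "-":
            return f"{complement(self.ref)}>{complement(self.alt)}"
        return self.mismatch

    @property
    def ref_tx(self) -> str:
        return complement(self.ref) if self.strand == "-" else self.ref

    @property
    def alt_tx(self) -> str:
        return complement(self.alt) if self.strand == "-" else self.alt

    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in "ACGT"
            and self.alt in "ACGT"
        )


@dataclass
class FilterReport:
    """Per-rule removal counts for one filtering stage.

    Invariant: ``retained + sum(removed.values()) == input_count``.
    """

    stage: str
    input_count: int
    retained: int
    removed: Dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.retained + sum(self.removed.values()) != self.input_count:
            raise AssertionError(
                f"filter report for {self.stage} does not conserve records: "
                f"{self.retained} + {self.removed} != {self.input_count}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "stage": self.stage,
                "input": self.input_count,
                "retained": self.retained,
                "removed": self.removed,
            },
            indent=2,
        )


# --- parsing -----------------------------------------------------------------

#: columns of the internal TSV dialect, in order
INTERNAL_COLUMNS = [
    "record_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript_id",
    "cds_offset",
    "region",
    "consequence",
    "clin_sig",
    "submitter_sigs",
    "n_submitters",
    "strand",
    "tx_pos",
    "codon",
    "codon_index",
    "window",
    "window_target",
]

_INT_FIELDS = {"pos", "cds_offset", "n_submitters", "tx_pos", "codon_index", "window_target"}


def _record_from_row(row: Mapping[str, object]) -> VariantRecord:
    kwargs: Dict[str, object] = {}
    for col in INTERNAL_COLUMNS:
        val = row.get(col)
        if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
            kwargs[col] = None
        elif col in _INT_FIELDS:
            kwargs[col] = int(val)
        elif col == "submitter_sigs":
            kwargs[col] = str(val).split("|") if val else None
        else:
            kwargs[col] = str(val)
    if kwargs.get("clin_sig") is None:
        kwargs["clin_sig"] = ""
    for key in ("gene", "transcript_id"):
        if kwargs.get(key) is None:
            kwargs[key] = ""
    if kwargs.get("strand") is None:
        kwargs["strand"] = "+"
    if kwargs.get("region") is None:
        kwargs["region"] = INTERGENIC
    return VariantRecord(**kwargs)  # type: ignore[arg-type]


#: default column map for the UCSC-style dialect: input column -> field
UCSC_COLUMN_MAP = {
    "chrom": "chrom",
    "chromStart": "start0",  # 0-based half-open
    "ref": "ref",
    "alt": "alt",
    "geneSymbol": "gene",
    "transcript": "transcript_id",
    "origName": "orig_name",
    "clinSign": "clin_sig",
    "molConseq": "consequence",
    "submitters": "n_submitters",
}


def _parse_orig_name(orig: str) -> Tuple[Optional[int], str]:
    """Parse an HGVS-like ``c.`` coordinate into a CDS offset and region.

    Plain positive integers (``c.1138G>A``) are coding offsets; UTR-style
    (``c.-12``, ``c.*45``) and intronic (``c.88+2``, ``c.89-1``) forms cannot
    be placed in the CDS and are routed to the gene_noncoding region.
    """
    if not orig or "c." not in orig:
        return None, GENE_NONCODING
    body = orig.split("c.", 1)[1]
    digits = ""
    for ch in body:
        if ch.isdigit():
            digits += ch
        else:
            break
    rest = body[len(digits):]
    if not digits or body.startswith(("-", "*")):
        return None, GENE_NONCODING
    if rest[:1] in {"+", "-"}:
        return None, GENE_NONCODING  # intronic offset
    return int(digits), CODING


def parse_variant_table(
    path: str,
    dialect: str = "internal",
    column_map: Optional[Mapping[str, str]] = None,
    errors: Optional[List[str]] = None,
) -> List[VariantRecord]:
    """Parse a variant table into records.

    Malformed rows are appended to ``errors`` (and logged), never silently
    dropped.  BED-style 0-based starts are converted to 1-based positions.
    """
    collect = errors if errors is not None else []
    if dialect == "internal":
        records = _parse_internal(path, collect)
    elif dialect == "ucsc_tsv":
        records = _parse_ucsc(path, column_map or UCSC_COLUMN_MAP, collect)
    elif dialect == "vcf":
        records = _parse_vcf(path, collect)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if not records:
        logger.warning("no records parsed from %s (dialect=%s)", path, dialect)
    for err in collect:
        logger.warning("malformed row in %s: %s", path, err)
    return records


def _parse_internal(path: str, errors: List[str]) -> List[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
    if missing:
        raise ValueError(f"unparseable header, missing columns: {missing}")
    records = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_record_from_row(row))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    return records


def _parse_ucsc(
    path: str, column_map: Mapping[str, str], errors: List[str]
) -> List[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if not set(column_map) & set(df.columns):
        raise ValueError("unparseable header: no mapped columns present")
    records = []
    for i, raw in enumerate(df.to_dict(orient="records")):
        row = {column_map[k]: v for k, v in raw.items() if k in column_map}
        try:
            cds_offset, region = _parse_orig_name(str(row.get("orig_name", "")))
            n_sub = row.get("n_submitters")
            records.append(
                VariantRecord(
                    record_id=f"ucsc_{i}",
                    chrom=str(row["chrom"]),
                    pos=int(row["start0"]) + 1,
                    ref=str(row["ref"]).upper(),
                    alt=str(row["alt"]).upper(),
                    gene=str(row.get("gene", "")),
                    transcript_id=str(row.get("transcript_id", "")),
                    cds_offset=cds_offset,
                    region=region if row.get("transcript_id") else INTERGENIC,
                    consequence=str(row.get("consequence")) or None,
                    clin_sig=str(row.get("clin_sig", "")),
                    n_submitters=int(n_sub) if n_sub not in (None, "") else None,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    return records


def _parse_vcf(path: str, errors: List[str]) -> List[VariantRecord]:
    from cyvcf2 import VCF

    records = []
    for i, v in enumerate(VCF(path)):
        try:
            alts = v.ALT or []
            if len(alts) != 1:
                errors.append(f"row {i}: non-biallelic record at {v.CHROM}:{v.POS}")
                continue
            clnsig = (v.INFO.get("CLNSIG") or "").replace("_", " ")
            clnsigconf = v.INFO.get("CLNSIGCONF")
            submitter_sigs = None
            if clnsigconf:
                submitter_sigs = [
                    s.split("(")[0].replace("_", " ")
                    for s in str(clnsigconf).split("|")
                    if s
                ]
            gene = v.INFO.get("GENEINFO") or ""
            if gene:
                gene = str(gene).split(":")[0]
            records.append(
                VariantRecord(
                    record_id=str(v.ID) if v.ID else f"vcf_{i}",
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF.upper(),
                    alt=str(alts[0]).upper(),
                    gene=str(gene),
                    clin_sig=clnsig,
                    submitter_sigs=submitter_sigs,
                    region=GENE_NONCODING if gene else INTERGENIC,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    return records


def to_tsv(records: Sequence[VariantRecord], path: str) -> None:
    """Write records in the internal TSV dialect (round-trip safe)."""
    rows = []
    for r in records:
        row = {}
        for f in fields(r):
            val = getattr(r, f.name)
            if f.name == "submitter_sigs" and val is not None:
                val = "|".join(val)
            row[f.name] = "" if val is None else val
        rows.append(row)
    df = pd.DataFrame(rows, columns=INTERNAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# --- filtering cascade --------------------------------------------------------


def apply_exclusions(
    records: Sequence[VariantRecord],
) -> Tuple[List[VariantRecord], FilterReport]:
    """Structural/annotation exclusions, applied in a fixed order.

    Rules (first match wins): downstream transcript variants; upstream
    transcript variants; no sequence alteration (ref == alt); no molecular
    consequence; misclassified SNVs (allele length != 1 or non-ACGT);
    mitochondrial records.
    """
    removed = {
        "downstream": 0,
        "upstream": 0,
        "no_sequence_alteration": 0,
        "no_consequence": 0,
        "misclassified_snv": 0,
        "mitochondrial": 0,
    }
    kept: List[VariantRecord] = []
    for r in records:
        if r.consequence == "downstream":
            removed["downstream"] += 1
        elif r.consequence == "upstream":
            removed["upstream"] += 1
        elif r.ref == r.alt:
            removed["no_sequence_alteration"] += 1
        elif not r.consequence:
            removed["no_consequence"] += 1
        elif not r.is_snv():
            removed["misclassified_snv"] += 1
        elif r.chrom in MITO_CHROMS:
            removed["mitochondrial"] += 1
        else:
            kept.append(r)
    report = FilterReport("exclusions", len(records), len(kept), removed)
    report.check()
    return kept, report


def _sig_is_pathogenic(sig: str) -> bool:
    return "pathogenic" in sig.lower()


def _is_conflicting(sig: str) -> bool:
    return "conflicting interpretations of pathogenicity" in sig.lower()


def filter_pathogenic(
    records: Sequence[VariantRecord],
    keep_unresolved_conflicts: bool = False,
) -> Tuple[List[VariantRecord], FilterReport]:
    """Keep clinically pathogenic records.

    A record is kept when its significance string contains the
    case-insensitive substring "pathogenic" ("Pathogenic", "Likely
    pathogenic", "Pathogenic/Likely pathogenic", ...).  Records reported as
    "Conflicting interpretations of pathogenicity" are kept iff at least one
    per-submitter significance is pathogenic; conflicting records with no
    submitter data are kept or dropped per ``keep_unresolved_conflicts`` and
    counted separately either way.
    """
    removed = {"not_pathogenic": 0, "conflict_not_pathogenic": 0, "conflict_unresolved": 0}
    kept: List[VariantRecord] = []
    n_unresolved_kept = 0
    for r in records:
        if _is_conflicting(r.clin_sig):
            if r.submitter_sigs is None:
                if keep_unresolved_conflicts:
                    kept.append(r)
                    n_unresolved_kept += 1
                else:
                    removed["conflict_unresolved"] += 1
            elif any(_sig_is_pathogenic(s) for s in r.submitter_sigs):
                kept.append(r)
            else:
                removed["conflict_not_pathogenic"] += 1
        elif _sig_is_pathogenic(r.clin_sig):
            kept.append(r)
        else:
            removed["not_pathogenic"] += 1
    if n_unresolved_kept:
        logger.info("kept %d unresolved conflicting records", n_unresolved_kept)
    report = FilterReport("pathogenic", len(records), len(kept), removed)
    report.check()
    return kept, report


def attach_cds_context(
    records: Sequence[VariantRecord],
    cds_fasta: Mapping[str, str],
    flank: int = 20,
) -> Tuple[List[VariantRecord], FilterReport]:
    """Attach codon and sequence-window context from the CDS FASTA.

    For coding records the CDS base at ``cds_offset`` must equal the
    transcript-oriented reference allele; mismatching records are dropped and
    counted (``cds_mismatch``), as are records whose transcript is absent
    from the FASTA.  Survivors gain the containing reading-frame codon, the
    0-2 position of the variant within it, and a +/-``flank`` nt reference
    window.  Non-coding records pass through unchanged.
    """
    removed = {"cds_mismatch": 0, "missing_transcript": 0, "offset_out_of_range": 0}
    kept: List[VariantRecord] = []
    for r in records:
        if r.region != CODING or r.cds_offset is None:
            kept.append(r)
            continue
        seq = cds_fasta.get(r.transcript_id)
        if seq is None:
            removed["missing_transcript"] += 1
            continue
        pos0 = r.cds_offset - 1
        if not 0 <= pos0 < len(seq):
            removed["offset_out_of_range"] += 1
            continue
        if seq[pos0] != r.ref_tx:
            removed["cds_mismatch"] += 1
            continue
        codon_start = (pos0 // 3) * 3
        codon = seq[codon_start : codon_start + 3]
        win_start = max(0, pos0 - flank)
        window = seq[win_start : pos0 + flank + 1]
        kept.append(
            replace(
                r,
                tx_pos=pos0,
                codon=codon if len(codon) == 3 else None,
                codon_index=pos0 - codon_start,
                window=window,
                window_target=pos0 - win_start,
            )
        )
    report = FilterReport("cds_context", len(records), len(kept), removed)
    report.check()
    return kept, report


def read_fasta(path: str) -> Dict[str, str]:
    """Read a multi-record FASTA keyed by the header token up to whitespace."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
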