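"""Optional integration: the filtering cascade on a real ClinVar archive.

The cohort-scale numbers (98,513 pathogenic SNVs in genes, the per-rule
exclusion counts, 78,923 CDS-consistent records, ...) require the pinned
external inputs and cannot be recomputed from synthetic data.  Given local
copies of the UCSC ClinVar track (hg38, 2021-11 archive), the matching
ClinVar VCF and the UCSC CDS FASTA, this script re-runs the same cascade
the synthetic pipeline uses and compares each stage count against the
archive's expected values at a 2% tolerance.

Inputs are local paths; nothing is downloaded.  Expected archive counts:

    input mutations        1,103,629
    SNV rows                 984,981
    downstream excluded          147
    upstream excluded          1,067
    no sequence alteration       237
    no molecular consequence   7,091
    misclassified SNVs           391
    mitochondrial              2,052
    in-gene SNVs             973,996
    pathogenic                98,513
    CDS-consistent            78,923

Usage:
    python analysis/07_clinvar_integration.py \
        --clinvar-tsv clinvarMain.txt --clinvar-vcf clinvar.vcf \
        --cds-fasta mane_cds.fa
"""

import argparse
import sys

EXPECTED = {
    "input": 1_103_629,
    "snvs": 984_981,
    "downstream": 147,
    "upstream": 1_067,
    "no_sequence_alteration": 237,
    "no_consequence": 7_091,
    "misclassified_snv": 391,
    "mitochondrial": 2_052,
    "in_gene": 973_996,
    "pathogenic": 98_513,
    "cds_consistent": 78_923,
}


def check(name, got, tolerance=0.02):
    exp = EXPECTED[name]
    ok = abs(got - exp) <= tolerance * exp
    print(f"{name:24s} got {got:>10,}  expected {exp:>10,}  "
          f"{'OK' if ok else 'OUT OF TOLERANCE'}")
    return ok


def main(argv=None):
    ap = argparse.ArgumentParser(
        description="Re-run the ClinVar filtering cascade on the pinned "
        "2021-11 UCSC archive (local files; nothing is downloaded)."
    )
    ap.add_argument("--clinvar-tsv", required=True,
                    help="UCSC ClinVar track table (clinvarMain, hg38 2021-11)")
    ap.add_argument("--clinvar-vcf", required=True,
                    help="ClinVar VCF with CLNSIG/CLNSIGCONF for submitter "
                    "resolution of conflicting records")
    ap.add_argument("--cds-fasta", required=True,
                    help="MANE-Select CDS FASTA keyed by transcript id")
    ap.add_argument("--tolerance", type=float, default=0.02)
    args = ap.parse_args(argv)

    from bescope.variant_io import (
        apply_exclusions,
        attach_cds_context,
        filter_pathogenic,
        parse_variant_table,
        read_fasta,
    )

    records = parse_variant_table(args.clinvar_tsv, dialect="ucsc_tsv")
    ok = check("input", len(records), args.tolerance)

    kept, rep = apply_exclusions(records)
    for rule in ("downstream", "upstream", "no_sequence_alteration",
                 "no_consequence", "misclassified_snv", "mitochondrial"):
        ok &= check(rule, rep.removed[rule], args.tolerance)
    ok &= check("in_gene", len(kept), args.tolerance)

    # attach per-submitter significances from the VCF for conflict records
    vcf_records = parse_variant_table(args.clinvar_vcf, dialect="vcf")
    submitters = {
        (r.chrom, r.pos, r.ref, r.alt): r.submitter_sigs for r in vcf_records
    }
    for r in kept:
        if r.submitter_sigs is None:
            r.submitter_sigs = submitters.get((r.chrom, r.pos, r.ref, r.alt))
    kept, _ = filter_pathogenic(kept)
    ok &= check("pathogenic", len(kept), args.tolerance)

    cds = read_fasta(args.cds_fasta)
    kept, _ = attach_cds_context(kept, cds)
    ok &= check("cds_consistent",
                sum(1 for r in kept if r.codon is not None), args.tolerance)

    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
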