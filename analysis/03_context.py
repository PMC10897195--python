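"""Sequence-context analysis: ADAR motif, PAM placement, bystander edits.

For G>A variants, checks the ADAR 5'-neighbor preference (no G immediately
5' of the edited A) — about 69% of coding and 58% of non-coding G>A
variants qualify.  For all editable variants, scans for NGG PAMs 12-16 nt
from the target (~30% have one) and counts same-type bystander bases in the
RNA +/-10 nt region and the DNA 5-base editing window, with
predictor-annotated pathogenic fractions.  Writes results/context.json.
"""

import argparse
import json
import os
import sys

import numpy as np

from bescope.pipeline import analyze_cohort
from bescope.synthetic_data import read_cohort


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/context.json")
    args = ap.parse_args(argv)

    cohort = read_cohort(args.cohort)
    res = analyze_cohort(cohort)
    m = res.metrics()
    keys = [k for k in m if "adar" in k or "pam" in k or "bystander" in k]
    payload = {k: m[k] for k in keys}
    payload["n_pam_in_range"] = res.n_pam_in_range
    os.makedirs(os.path.dirname(args.out), exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"ADAR motif present: {m.get('pct_adar_motif_coding', float('nan')):.1f}% "
          f"(coding G>A), {m.get('pct_adar_motif_noncoding', float('nan')):.1f}% "
          f"(non-coding G>A)")
    print(f"NGG PAM 12-16 nt away: {m.get('pct_pam_present', float('nan')):.1f}% "
          f"of editable variants")
    print(f"mean bystanders, G>A coding: "
          f"{m.get('mean_rna_bystanders_g_a', float('nan')):.2f} A's in +/-10 nt, "
          f"{m.get('mean_rna_pathogenic_bystanders_g_a', float('nan')):.2f} "
          f"predicted pathogenic")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    sys.exit(main())
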