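"""Headline summary and clinical stratifications.

Aggregates everything into the cohort-level picture: fractions editable per
category, guide-specificity (MIT > 50) among PAM-bearing variants,
submitter-count and population-frequency stratifications, and the
liver/brain tissue-restricted gene sets.  Writes results/summary.json.
"""

import argparse
import json
import os
import sys

from bescope.pipeline import analyze_cohort
from bescope.summarize import filter_by_frequency_presence
from bescope.synthetic_data import read_cohort


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", default="results/cohort")
    ap.add_argument("--out", default="results/summary.json")
    args = ap.parse_args(argv)

    cohort = read_cohort(args.cohort)
    res = analyze_cohort(cohort)
    m = res.metrics()
    m["n_in_frequency_table"] = len(
        filter_by_frequency_presence(res.records, cohort.freq)
    )
    os.makedirs(os.path.dirname(args.out), exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(m, fh, indent=2, sort_keys=True)
    print(f"{m['pct_correctable']:.1f}% of pathogenic SNVs correctable by some "
          f"base editor ({m['pct_direct_editable']:.1f}% direct + "
          f"{m['pct_complementary_editable']:.1f}% complementary); "
          f"{m['pct_improvable']:.1f}% improvable -> "
          f"{m['pct_amendable_any']:.1f}% amendable overall")
    print(f"MIT specificity > 50: {m.get('pct_mit_above_50', float('nan')):.1f}% "
          f"of PAM-bearing variants")
    print(f"{int(m['n_liver_genes'])} liver-restricted and "
          f"{int(m['n_brain_genes'])} brain-restricted genes")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    sys.exit(main())
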