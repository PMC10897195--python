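"""Generate the synthetic study cohort.

Builds a seeded 2,000-variant pathogenic-SNV cohort whose composition
mirrors a ClinVar-style pathogenic set (mismatch-type and consequence
fractions, ADAR/PAM/bystander/off-target context, predictor and score
tables) and writes it, together with its ground-truth manifest, under
results/cohort/.
"""

import argparse
import sys

from bescope.synthetic_data import generate_cohort, write_cohort


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-variants", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/cohort")
    args = ap.parse_args(argv)

    cohort = generate_cohort(args.n_variants, args.seed)
    paths = write_cohort(cohort, args.outdir)
    t = cohort.truth.cohort
    print(f"cohort: {t['n_variants']} pathogenic SNVs "
          f"(+{t['n_distractors']} filter distractors), seed {args.seed}")
    print(f"planted categories: {t['category_counts']}")
    print(f"wrote {len(paths)} files to {args.outdir}")


if __name__ == "__main__":
    sys.exit(main())
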