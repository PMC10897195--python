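# Methods

## The model

Deaminase base editors admit two chemistries, modeled throughout on the
mRNA-sense strand in DNA alphabet (U ≡ T): A→G (adenosine deamination,
read as inosine/guanosine) and C→T (cytidine deamination). Applied to the
twelve ordered SNV mismatch types this yields a four-way partition:

| category | mismatch types | mechanism |
|---|---|---|
| direct | G>A, T>C | deaminate the mutant base itself |
| complementary | C>T, A>G | deaminate the paired base on the opposite DNA strand; mismatch repair completes the correction |
| improvable | any of the other 8, missense/nonsense | re-edit the mutant codon toward a better amino acid |
| not amendable | remainder | — |

Scope rules: cytoplasmic RNA editors only reach exonic (mature-mRNA)
positions; nuclear RNA editors (ADAR p110 recruitment) also reach
intronic/UTR positions of the pre-mRNA; DNA editors reach any position in a
gene, on either strand. Direct and complementary calls are mutually
exclusive by construction; the reporting precedence is direct >
complementary > improvable. Mismatch orientation for RNA calls is
transcript-sense (genomic alleles complemented on − strand transcripts);
censuses default to genomic orientation, with a switch.

## Filtering cascade

Mirrors a ClinVar-style curation workflow, in order: (1) structural
exclusions — downstream/upstream transcript variants, rows with no sequence
alteration (ref = alt), rows with no molecular consequence, rows
misclassified as SNVs (allele length ≠ 1), mitochondrial rows; (2) the
pathogenicity phrase rule — keep any significance string containing the
case-insensitive substring "pathogenic", with "conflicting interpretations
of pathogenicity" resolved by requiring at least one pathogenic
per-submitter report (unresolved conflicts configurable, dropped by
default); (3) CDS consistency — the transcript CDS base at the reported
offset must equal the transcript-oriented reference allele, otherwise the
record is dropped and counted. Every stage emits a conservation-checked
`FilterReport` (retained + removed = input). Note the phrase rule is
deliberately literal: "Pathogenic/Likely pathogenic" is kept even though it
also matches "likely"; only the conflicting-interpretations string gets the
submitter treatment.

## Context analysis

**ADAR motif.** For an edited A (transcript orientation, mutant sequence),
the 5′ neighbor must exist and not be G. A target at the sequence boundary
fails the motif and is flagged.

**PAM discovery.** The NGG motif is searched on both orientations of the
mutant context. Distance is the number of nucleotides between the target
base and the *nearest* base of the PAM trinucleotide (the N, since the
protospacer lies 5′ of NGG); the accepted range is [12, 16] inclusive, a
configurable knob. The 5-base editing window is the set of protospacer
positions at distances 12–16 from the PAM — window and distance filter are
one constraint, so the window always contains the target. Hits whose
window would leave the sequence are discarded.

**Bystanders.** RNA editors: occurrences of the editable base within ±10 nt
of the target (our reading of "the 20 nucleotides surrounding the
variant"), target excluded, truncated at ends. DNA editors: occurrences
within the editing window. For complementary variants the edited strand is
the antisense one; counting the complementary base on the sense strand is
equivalent to reverse-complementing the window, and that is what the
pipeline does. Each bystander implies a fixed alteration (A→G/C→T on the
edited strand), looked up in the predictor table; missing entries count as
not pathogenic and are logged, because missense predictors only cover
amino-acid-changing substitutions (in particular, non-coding bystanders are
never covered).

## Off-target search

The guide-adhesion query is the variant's ±20 nt context (41 nt total)
carrying the **mutant** allele — the guide is designed against the patient
sequence. Subjects are the transcript set; each is searched in both
orientations with Smith–Waterman local alignment (match +1, mismatch −1,
gap −2 linear; identity = matches / alignment columns, gap columns in the
denominator). Alignments are extracted greedily best-score-first with
masking (Waterman–Eggert style) until the best remaining score drops below
⌈min_len·(2·min_identity − 1)⌉, the minimum score any passing hit could
have; alignments with ≥ 20 columns and ≥ 85 % identity are reported. The
greedy semantics matter at the threshold: a full-length 82.9 %-identity
copy *is* the best local alignment of its region, fails the identity test,
and is masked — so it correctly yields zero hits even though a trimmed
sub-window of it would pass in isolation. The hit covering the query's own
locus is flagged `is_self` and excluded from counts. Ties in the DP are
broken deterministically (best cell: highest score, then smallest subject
end, then smallest query end; traceback prefers diagonal over up over
left), and the fill is numba-jitted.

For cohort-scale censuses an exact k-mer seed (k = 13) selects which
subjects are aligned at all; a subject sharing no 13-mer with the query (in
either orientation) is skipped. Any alignment containing a ≥13 nt exact run
is guaranteed to be seeded; the synthetic generator plants its duplicates
accordingly, so seeded and exhaustive modes agree on all planted material.
Exhaustive mode remains the default for single queries and is what the
brute-force oracle tests exercise.

## Codon improvement

For a missense/nonsense variant that no editor can revert: enumerate all
2^k − 1 edit subsets of the mutant codon under {A→G, C→T}, translate each
novel codon, drop stops (creating a nonsense variant is never an
improvement), score each novel amino acid, keep candidates strictly above
the mutant baseline, and select by maximum score, then minimum edit count,
then lexicographically smallest novel codon (the last tie-break is our
determinism choice; the first two are the algorithm's definition).

Scorers. *Matrix mode*: BLOSUM62 (via Biopython, restricted to the 20
standard residues; entries −4…11), candidate score = B62(ref_aa, novel_aa),
baseline = B62(ref_aa, mut_aa). Stop codons are outside BLOSUM62, so pairs
involving STOP take sentinel values — STOP↔STOP = −10^6, one-STOP pairs =
−10^6 + 1 — guaranteeing any escape from a premature stop outranks keeping
it while never entering arithmetic with real entries (callers compare, not
sum; `score_delta_distribution` refuses sentinel-bearing results).
*Site-table mode* (SIFT-style): per-site tolerance scores in [0, 1];
candidates at or below the 0.05 floor are dropped, candidates with no table
entry are skipped (tolerance predictors do not cover every substitution),
and a mutant stop takes baseline 0 with the floor waived — any scored
amino acid escape qualifies.

Two consequences of the chemistry, both verified exhaustively in the test
suite: A→G editing cannot create a stop codon, and each stop codon's only
non-stop destination is TGG (Trp). A third, found during implementation:
restoring the *reference codon* by editing is only possible when the
variant itself was direct-editable, so the `protein_level_correction` flag
(novel amino acid = reference amino acid) can never fire for a true
improvement candidate; it is retained for codon-level use. Candidates that
are complementary-editable are counted under complementary editing, not
improvement — improvement is run on the variants nothing can revert.
Synonymous, initiator-codon and stop-lost variants are excluded from
candidacy. A warning flag marks substitutions that plausibly disrupt
post-translational modification sites (S/T/Y → G/A/C, K → R/G).

## Synthetic cohorts

The generator emulates every input: transcriptome (random ORFs: ATG start,
no internal in-frame stops, stop end), variant table with filter-fodder
distractor rows, per-submitter VCF, predictor/site-score/MIT/frequency
tables, and a gene × tissue TPM matrix. Every planted attribute is
*constructed*, not sampled-then-measured, and recorded in a manifest, so
recovery tests are exact rather than statistical (the one exception:
per-bystander pathogenicity classes are Bernoulli draws whose realized
counts are recorded in the manifest — the planted *rate* is checked at 3
standard errors, everything else exactly).

Construction guarantees, per variant: the ±10 nt bystander zone is filled
without the variant's editable base, then exactly the sampled number of
bystanders is written in (binomial(20, p) with p matching the target means
4.6/5.3 for RNA; binomial(4, mean/4) within the DNA window); the PAM band
(10–21 nt out) is kept free of GG/CC dinucleotides so the planted PAM —
in-range at 12–16 or an out-of-range decoy at 11/17, with non-G/C guard
bases — is the only one in range; the 5′ neighbor realises the planted
ADAR status (chosen within the codon when the neighbor is intra-codon).
Off-target duplicates are 41-mer copies planted in decoy transcripts with
fixed mismatch patterns realising identities 1.0, 0.902, 0.854 (hits) and
0.829 (non-hit); passing patterns keep a ≥13 nt exact run, the 0.829
pattern's longest run is 5. A deduplication pass then rewrites filler
bases until no unintended 13-mer is shared between any query window and
any subject, which makes the 91 % zero-off-target fraction exact by
construction. Improvable variants get codon set-ups (found by enumeration)
whose minimum-edit candidate realises the planted chemistry mode, and site
scores that make exactly that candidate win (mutant ~U(0, 0.04), chosen
novel = mutant + U(0.07, 0.37) — mean gain 0.22 — all other reachable
residues below the 0.05 floor); non-improvable nonsense candidates simply
lack the Trp row, mirroring incomplete tolerance-predictor coverage.

Default composition (a deliberate portrait of a pathogenic ClinVar-style
cohort): 81 % coding; per-region mismatch fractions giving 29.6 % direct /
29.1 % complementary overall; coding consequences ≈ 60 % missense, 38 %
nonsense, small synonymous/initiator/stop-lost classes (shifted to missense
where a mismatch type cannot realise them — e.g. no `*>C` type can create
a stop codon); ADAR-ok 69 %/58 % (coding/non-coding G>A); PAM presence
30 % of editable variants plus 5 % out-of-range decoys; MIT > 50 in 77 %
of PAM-bearing variants; 9 % of direct coding variants with a planted
off-target hit and 4 % with the sub-threshold decoy; improvable 4.1 % of
the cohort with A-only : C-only : combined ≈ 77 : 22 : 1 and stop escapes
all A-only; submitter count ≥ 3 in 19.4 %; gnomAD-style presence 24 %; 60
liver-restricted and 300 brain-restricted genes plus
high-everywhere decoys rejected by the strict thresholds. One integer seed
drives independent named streams per stage, so regeneration is
bit-identical and adding a stage never perturbs earlier ones.

What the generator does not emulate: real genomic base composition and
repeat structure, linkage, transcript isoform overlap, strand-negative
genes (strand handling is unit-tested separately), realistic predictor
score distributions, and the correlation structure of real ClinVar
annotations. Passing recovery tests therefore demonstrate the pipeline's
correctness on inputs whose truth is known, not the field accuracy of any
threshold.

## Problem sizes and numerics

The standard cohort is 2,000 variants over ~1,700 transcripts of 240 nt —
large enough that every planted class (including the 1-in-2,000 combined-
chemistry improvables and the four PAM boundary distances) is populated,
while the whole suite runs in seconds. Strict inequalities are used
exactly where stated: score > baseline, site score > 0.05, MIT > 50,
TPM > 10, mean < 10; identity and alignment-length thresholds are ≥.
Expression thresholds reject exactly-at-threshold genes on both sides.
Degenerate inputs: empty cohorts, empty tables, boundary targets and
truncated windows return empty/flagged results rather than errors; codon
positions at transcript edges truncate their windows.

## Known limitations

- The PAM distance anchor ("12–16 bases away") is interpreted as the gap to
  the nearest PAM base; the range is configurable for sensitivity checks.
- The off-target search is transcript-scale, not genome-scale; DNA-level
  off-targets enter only through the precomputed MIT score filter.
- Editing efficiency, position effects inside the editing window, non-NGG
  Cas variants and prime editing are out of scope.
- The 40-base adhesion region is realised as 20 nt per side plus the
  variant base (41 nt); whether the variant base itself was meant to be
  included is ambiguous, and the flank is a knob.
- Mitochondrial variants are excluded by the cascade, not analysed.
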