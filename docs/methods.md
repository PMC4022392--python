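# Methods

This note documents the models, conventions and numerical choices behind
`varconcord`, and what the synthetic-data validation does and does not
establish about real sequencing data.

## Variant model and normalization

The unit of comparison is a normalized bi-allelic variant
(chrom, 1-based pos, REF, ALT).  Multi-allelic VCF records are decomposed
into one record per alternate allele; each decomposed record's genotype
class is derived solely from the copy count of its own alt allele
(2 → hom-alt, 1 → het, 0 → hom-ref, any missing allele → no-call), so a
`1/2` genotype yields two het records.  This keeps every record
self-contained under strict-equality joins; the cost is that the hom-ref
class of a decomposed sibling record does not mean "reference-confirmed".
Haploid genotypes (sex chromosomes in a gender-masked pipeline) map to the
hom-alt/hom-ref classes; no separate hemizygous class exists.  Half-calls
such as `0/.` are treated as no-calls.  Symbolic alleles are dropped with
a logged count; MNPs are classed OTHER and excluded from SNV/indel
partitioned tables.

Normalization trims the shared allele suffix, then the shared prefix
keeping one anchor base, then left-shifts indels to their fixpoint against
a reference context window: while the alleles share a terminal base the
pair is right-trimmed, extending left through the reference whenever an
allele would become empty.  The algorithm is idempotent and
haplotype-preserving; the unit tests verify both against a brute-force
enumeration of all parsimonious representations in the window.  If the
window's left edge is reached before the fixpoint is proven, the operation
fails with a request for a larger window rather than returning a possibly
non-leftmost variant.

FILTER semantics: anything other than `PASS` or `.` marks a call FILTERED.
`.` counts as PASS because truth sources (arrays, validated panels) carry
no filter column.  Concordance treats FILTERED calls as no-calls; the
uniformity analysis deliberately does not (see below).

## Concordance metrics

Joins are strict variant equality inside target intervals (BED
convention: 0-based half-open; a call at 1-based pos p is kept iff p−1 is
covered).  Different representations of the same complex variant are *not*
recognized as concordant — a deliberate reproduction of the pipeline
limitation the method is designed to measure, mitigated only by shared
left-alignment of both callsets.

The concordance denominator is restricted to sites genotyped in both
callsets (no-call and absent excluded); because the variant caller emits
no hom-ref records, hom-ref rows occur only with truth sets that report
them, which avoids inflating concordance with easy hom-ref agreement.
Undefined ratios (empty denominators) are reported as absent values.

Precision depends on whether the truth set is *exhaustive* — declared on
the truth callset — i.e. guaranteed to report every variant inside its
intervals (arrays, validated panels, high-confidence reference sets).
Against an exhaustive truth, test-only non-reference calls count against
precision; against a non-exhaustive truth they are excluded from the
denominator and reported separately (`n_test_only_nonref`).  Under the
exhaustive convention the duality precision(A,B) = NRC(B,A) holds exactly,
which the tests assert on random fixtures.  Replicate-vs-replicate
comparisons use this convention and score each pair in both directions;
concordance is symmetric by construction, NRS/NRC/precision are not.

## Panel site-level evaluation

Truth sites carry a status of `nonref` or `ref-confirmed`.  Each nonref
truth site is classified tp (exact key match among PASSing test calls),
diff_allele (some PASSing test call at the position, none with the
matching alt), or fn; ref-confirmed sites with no test call are tn.
Unmatched test calls are tallied as a combined FP/"excess positive" count
because panels cannot conclusively refute every novel call; those at
ref-confirmed sites additionally enter the specificity denominator.
Site-level sensitivity counts different-allele sites as detected in both
numerator and denominator — the convention that exactly reconciles the
published per-replicate count columns — while the genotype-aware NRC
credits only genotype-exact matches.  The FN report annotates each missed
site with the longest single-base run overlapping the variant span; runs
of ≥ 10 bp are flagged as homopolymer context, the threshold matching the
shortest run implicated among published missed indels.

## Callable loci and coverage

A base is callable iff depth ≥ 20 and mapq0/depth ≤ 0.10 — both
boundaries inclusive, a literal reading of "a minimum of 20-fold" and "no
more than 10%".  Bases absent from the coverage track have zero depth and
fail the depth test (their MAPQ0 fraction is undefined but irrelevant).
Depth-threshold summary fractions and the mean (zero-depth bases
included) are computed over the un-flanked target intervals; the callable
fraction of coding exons uses targets expanded by a 100 bp flank, merged
after expansion, because variants are called in the flanks.  The
squared-off callable set is the per-base AND of the replicates' callable
regions.  Percentages are computed at full precision and rounded to one
decimal only for display.

The core consumes per-base TSV tracks (chrom, pos, depth, MAPQ0 count)
rather than alignments, which keeps the logic testable at desk scale; an
alignment-derived track can be produced externally (e.g. with samtools)
without changing any downstream code.

## Quality-threshold sweeps

At each threshold t, scored calls with VQSLOD ≥ t are treated as PASS and
all others as no-calls, and precision/NRC recomputed.  The ≥ convention
is a choice; with continuous scores the alternative (>) differs only on
ties.  Calls without a score are excluded from the sweep and counted
separately (the pipeline being characterized applies fixed filters rather
than VQSR to exome indels, so score-free calls have no defined position on
the curve).  Automatic threshold grids are the distinct observed scores,
deterministically thinned by quantile to ≤ 200 points.  Sweeps are per
variant class (SNV and indel separately).  The marginal table counts the
newly admitted agreeing (ΔTP) and disagreeing/unconfirmed (ΔFP) calls
between consecutive thresholds and flags the interval(s) where ΔTP:ΔFP
crosses 1 — the natural inflection point for filter placement.

## Replicate reproducibility

Uniformity partitions the union of emitted variant keys by the number of
replicates carrying them.  Presence is *filter-blind*: a called-but-
filtered variant still counts, because variation in which variants the
caller emits is a different failure mode from variation in filtering.
This deliberately differs from the concordance metrics' filtered→no-call
rule.  The union denominator is the raw union of emitted sites,
optionally restricted to an interval scope (e.g. the squared-off callable
set, or its intersection with high-confidence regions).

Comparison kinds are derived from replicate provenance: same run and
machine → intra-run; same machine, different run → inter-run; different
machine → inter-machine; different mode → inter-mode; different library →
inter-library.  Kinds are non-exclusive; the single-kind "primary" label
is cosmetic.  Because the published figures defining the library
assignments are schematics, the packaged design template chooses library
assignments consistent with the published pair classifications and pair
counts (31 exome pairs from 7+5 replicates, 18 genome pairs from 6+3);
the classification logic itself is what the tests validate.

The regression models the symmetric pairwise concordance as an additive
function of kind indicators with per-sample control indicators.  The
three run/machine kinds partition the pairs, making the joint design
collinear with the intercept; the joint model therefore drops kinds as
baseline categories (intra-run first) until full rank, and its
coefficients read as additive concordance changes relative to that
baseline.  The overall test is a nested F-test against the sample-only
null; per-kind p-values come from one-kind-at-a-time regressions (kind +
sample controls), each compared against a Bonferroni-corrected threshold
of 0.05 divided by the number of kinds that vary in the design (4 for the
genome family, where no rapid-mode replicates exist and inter-mode is
constant).

## Synthetic-data generator

The corruption process applies, per truth site and independently, miss
(probability `p_miss`, default 0.04; indels at marked homopolymer keys get
an additional dropout, default 0.9, reflecting how single-base indels in
long runs are seen in too few reads to call), then different-allele
substitution (`p_diffallele`, 0.002), zygosity perturbation het↔hom-alt
(`p_gterr`, 0.01), and filter flagging (`p_filtered`, 0.01); false
positives arrive uniformly over unoccupied interval bases at `p_fp_per_kb`
(0.1).  The fixed order and independence make the first-order
expectations exact: NRS = (1−p_miss)(1−p_diffallele)(1−p_filtered) and
NRC = NRS·(1−p_gterr), which the tests verify within three binomial
standard errors at n = 10⁵.  Defaults were chosen once to echo the regime
the method operates in — NRS near 0.95, replicate concordance near 0.99,
indel uniformity well below SNV uniformity.  Quality scores are Gaussian
per latent status (true N(10, 3²) vs artifact N(0, 3²)) with closed-form
survival functions as the ROC oracle.  The batch-effect model generates
pairwise concordances as base 0.99 minus active kind decrements (default:
inter-library 6×10⁻⁴) plus N(0, 2×10⁻⁴²) noise, clipped to [0, 1].

What the generator does *not* emulate: linkage and allele-frequency
structure, reference-context-dependent error processes (beyond the
homopolymer flag), structural variants and the artifactual calls they
shed, multi-sample joint-calling effects, and read-level noise.  Passing
tests therefore establish the correctness of the bookkeeping, metric
algebra and statistical machinery under a known generative model — not
the empirical performance of any sequencing pipeline.  Published
quantities that require the original sequencing data (coverage tables,
uniformity percentages, the empirical regression p-values) are
correspondingly out of scope; the regression and uniformity properties
are validated as parameter-recovery and directional checks instead.

## Problem sizes and numerical choices

The test suite runs the metric/oracle equivalence on 1,000 random pairs
of up to 1,000 sites, parameter recovery at 10⁵ sites, the PR/ROC
comparison at 5×10⁴ true calls (DKW envelope at α = 10⁻⁶ for the survival
function; 0.02 absolute tolerance for the mixture precision where the
expected denominator is ≥ 500 calls), callable-loci oracle equivalence on
a 10⁵-base track, and a 1,000-repetition null simulation for the
regression's type-I error (asserted within three binomial standard errors
of 0.05).  All randomness is seeded; generators are pure functions of
their parameters and seed.  Chromosome ordering is natural
(chr1…chr22, chrX, chrY, chrM, then unknown contigs lexicographically);
interval sets are canonicalized (sorted, merged, half-open) on
construction; metric ties and boundary cases (exactly 20× depth, exactly
10% MAPQ0, thresholds equal to a score) are resolved inclusively as
documented above.
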