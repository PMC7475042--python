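# Methods

## The estimation problem

The *NOTCH2NL* genes arose from segmental duplications of the 5' end of
*NOTCH2* and are nearly sequence-identical to it and to each other. Reads
from any family member align interchangeably across the loci, so per-locus
copy number, gene-conversion status and variant dosage must all be inferred
from pooled signals: total read depth, and allele depths at positions where
one paralog differs from the rest (SUNs). `paralocus` implements that
inference as a pipeline of small, separately testable estimators.

## Model and procedure

**Combined allele count.** With the duplicate loci masked from the
reference, depth at a multicopy-region position is proportional to the
number of family alleles spanning it, while a *NOTCH2*-only region carries
exactly two alleles in every genome. The estimator is

    ratio = mean depth(multicopy) / mean depth(single-copy)
    total alleles = 2 × ratio,

means taken per position after subtracting repeat intervals. Defaults:
single-copy chr1:119,908,310–119,989,035; multicopy
chr1:119,990,490–120,087,745 (hg38, both configurable). No GC or
mappability correction is applied; the depth model the estimator assumes is
locally uniform coverage.

**SUN derivation.** Each paralog is globally aligned to the parent (match 1,
mismatch −1, gap open −2, gap extend −0.5; pairs under 80% identity are
rejected as mis-specified input). An alternate allele at a parent column is
a SUN when exactly one paralog carries it; uniqueness is decided per
(position, allele), so two different alternates at one column can each be a
SUN. Indels are left-aligned; deletions anchor at the first deleted parent
base, insertions at the preceding one. Columns where *all* paralogs share
one alternate mark the parent uniquely; `derive_suns(...,
include_parent=True)` emits these as parent markers, whose frequency in a
masked-reference pileup is read from the REF allele-depth column (the
parent's base is the reference). SUNs are restricted to the maximal-duplicon
region, default chr1:119,990,474–120,087,745; the region is configurable
because the upstream end is better constrained than the downstream one.

**Per-paralog counts.** For sample *s* and SUN *i*, frequency
`f_si = AD_si / DP_si` (missing when DP = 0, never zero-filled). Across a
cohort, a SUN is retained iff

    median_s ( f_si / e_i ) > 0.67   (strict),

where `e_i` is the expected fraction, default 2 carrying alleles / 10 total.
The threshold is applied to the expectation-normalized frequency because raw
frequencies differ per locus; the statistic (median vs mean), the expected
fraction and the threshold are all configurable, and a single-sample cohort
passes everything with a warning. Then, with `T` the integer combined count,

    count(locus) = round(mean_i f_si × T)    for NOTCH2, NLR, NLC
    remaining    = T − (N2 + NLR + NLC)
    NLA : NLB    = mean SUN frequency ratio, largest-remainder rounding.

Largest-remainder rounding guarantees the five counts sum to `T` exactly;
ties in the fractional parts break toward *NLA* (deterministic). A negative
remainder is clamped to zero and flagged rather than raised, since noisy
data can produce it. All rounding in the package is half-away-from-zero, so
an estimated 2.5 alleles becomes 3, never 2.

**NOTCH2 > NOTCH2NLR conversion correction.** Gene conversion that
overwrites *NLR* alleles with *NOTCH2* sequence inflates *NOTCH2* and
deflates *NLR* complementarily without changing copy number. When the
estimate shows `NOTCH2 = 2+k` and `NLR = 2−k` (k ≥ 1), k alleles are
reassigned back and the genotype is flagged; anything non-complementary is
left alone.

**Conversion profiling.** `frequency × T` per SUN gives the allele-count
track; the cohort track is the per-SUN median across samples. Segments are
maximal runs of ≥ `min_run` (default 3) consecutive same-paralog SUNs whose
rounded count deviates from the default (2) in one direction; magnitude is
the median rounded deviation. The run-length rule is this package's own
segmentation — the underlying phenomenon is usually judged from median
tracks by eye, which is not reproducible — and both parameters are exposed.
In the 5' region, where *NLB* has no SUNs, its track is inferred as
`pair total − NLA count`, clamped at zero.

**Variant dosage.** `round(a/d × t)` for a variant seen in `a` of `d`
pooled reads with `t` family alleles. For exome-style data mapped to the
unmasked genome, the variant frequency is the read depth at the paralogous
position whose reference carries the variant allele, divided by the summed
depth over all five positions (multimapping reads included); the built-in
position tables cover the Exon1 A-type start-codon variant (annotated on
*NLA*), the Exon2 splice-site variant (annotated on *NLB*) and the N232S
site (ancestral at every reference locus, so only pooled AD-based dosage
applies to it). Exon1 class counts per genome: A-type and C-type from their
variant-read fractions; B-type inferred as `A/B pair total − A-type`,
clamped at zero — valid only where the pair carries A- or B-type alleles.

**Population statistics.** The expected allele-count distribution under two
independently segregating biallelic loci (an AABB × AABB cross) has support
0–4 with probabilities 1:4:6:4:1 /16; samples draw the category first and
add Gaussian jitter (sd 0.34 at n = 2,790 on the count scale; sd 0.034 at
n = 50,000 on the frequency scale, support 0–0.4). The frequency-scale
generator accepts per-locus loss rates for *NLC* and *NLR*: each simulated
individual loses an allele with the given probability, shrinking its
frequency denominator from 10 to 10 − losses before jitter; the closed-form
mean of this mechanism is implemented alongside and used as a test oracle.
Loss rates are estimated from a genotyped cohort, not assumed.
Kruskal–Wallis uses the tie-corrected H with a chi-square p (all-tied input
is defined as H = 0, p = 1); Dunn's z uses the standard tie-corrected
variance with two-sided normal p values; Holm is the step-down adjustment
with running maximum, capped at 1.

## Synthetic data

The generator emulates exactly what the pipeline consumes, at the
statistical level the estimators assume:

- depth per position ~ Poisson(base_depth × local allele count / 2), local
  count being 2 in the single-copy region and the sum of spanning duplicons
  in the multicopy region (duplicon extents configurable);
- DP at SUN/variant sites ~ Poisson(base_depth × total/2), supporting reads
  ~ Binomial(DP, carrying/total), with conversion tracts transferring SUN
  carriage between donor and acceptor (copy-neutral) and point variants
  planted at configured allele counts;
- per-individual seeds derived deterministically from (cohort seed, index).

Presets encode the study conditions: `modern_human_standard` (ten alleles,
two per locus, both *NLC* alleles C-type), `neanderthal_altai_like` (eleven
alleles — the extra A/B allele is placed on *NLA*, since pooled data cannot
resolve which of the pair gained it — a near-full-length *NOTCH2*→*NLR*
conversion tract on one allele, M40I on one allele, N232S on two) and
`denisova3_like` (homozygous *NLR* deletion, six *NOTCH2NL* alleles all
carrying the C-type Exon1 variant, E258A on two alleles). Base depth
defaults to 30×.

What the generator does **not** model: sequencing error, ancient-DNA damage,
GC and mappability bias, library-size variation, alignment artifacts at
paralog boundaries, and real SUN ascertainment noise. Passing tests
therefore demonstrate the correctness and calibration of the estimators
under their own statistical assumptions, not robustness to real archaic
sequencing data.

## Numerical choices and problem sizes

- Rounding: half away from zero everywhere an allele count is produced.
- Apportionment ties: largest-remainder, earlier locus first.
- Degenerate inputs: DP = 0 → missing; all-tied Kruskal–Wallis → H = 0,
  p = 1; zero group frequency denominators → missing, not 0; single-sample
  population filter → pass-through with warning.
- The test suite simulates full-scale regions (≈180 kb) for the preset
  recovery checks and 15–40 kb regions for the replicated property suites
  (100 replicates each), keeping the whole suite around 15 s.

## Known limitations

- Single-site variant dosage is binomially limited: at ~150 reads the
  rounding interval for a 2-of-11 variant is only ≈1.5 SE wide, so per-site
  recovery caps near 87% there and reaches ≥95% only above ≈250–350 reads.
  The pipeline-level per-locus counts do not share this limit because they
  average tens of SUNs.
- The Exon1 class counts rest on a single position each; at 30× the
  per-genome estimate is correct ≈ 90% of the time and the cohort median is
  the robust quantity.
- The B-type inference `pair total − A-type` is wrong for genomes whose A/B
  pair carries C-type sequence (the Denisova3-like configuration); the
  pipeline leaves Exon1 class counts unreported when the A-type site is
  absent rather than report a misleading complement.
- Conversion segmentation is SUN-resolution: boundaries land on the
  innermost SUNs a tract covers, so boundary precision is one inter-SUN
  spacing.
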