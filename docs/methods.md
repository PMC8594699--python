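# Methods

`amplimeth` analyses ultra-deep paired-end bisulfite sequencing of long PCR
amplicons, the design used to resolve cell-type-mosaic methylation in complex
tissues such as the insect brain: a handful of target genes, nested-PCR
amplicons of roughly 400–550 bp carrying 10–15 CpGs each, and 10⁴–10⁵ read
pairs per amplicon and condition library. At that depth the data support
*per-molecule* analysis: every read pair is reduced to the ordered binary
vector of its CpG states (its methylation pattern, or epihaplotype), and the
biology is read off the frequency distribution of those patterns rather than
off per-CpG averages alone.

## Pipeline model

**Template preparation.** Each amplicon is described by its genomic top-strand
sequence; CpG sites are found by a dinucleotide scan, and an in-silico
bisulfite-converted template is derived by rewriting every non-CpG C to T
while keeping CpG Cs. Amplicon PCR of converted DNA fixes the strand, so only
the top-strand (C/T) conversion space is modelled; reverse-strand (G/A) logic
is out of scope. Templates containing N are rejected because pattern positions
must be certain.

**Pair selection.** A read pair is assigned to an amplicon when the 30 nt of
read 1 starting at position 4 (1-based) exactly match the last 30 nt of the
forward nested primer, and the same holds for read 2 against the reverse
primer. Matching is exact by design — the nested primer is the only sequence
the library guarantees — and the three skipped leading bases absorb
non-template read starts. Exactness makes primer-window sequencing errors a
source of pair loss (≈15–20% at the default error rates), never of
misassignment.

**Alignment.** Each mate (primer tag stripped, read 2 reverse-complemented) is
aligned to the converted template with a semi-global affine-gap aligner (free
end gaps on the read): match +2, mismatch −3, gap open −5, gap extend −2, with
a gap of length k costing 5 + 2k. The scoring is bisulfite-aware and
asymmetric: read T over template C is a full match (an unmethylated,
converted C), while read C over template T is a mismatch. Traceback ties
prefer diagonal, then up, then left, so alignments are deterministic. Because
primer anchoring fixes each read's template register, the pipeline runs the
identical dynamic program inside a diagonal band (half-width 32 columns); a
traceback touching the band edge, or a banded score below 1 point per base,
triggers a full-matrix realignment. Tests assert banded and full results
agree on indel-carrying reads.

**Merging.** The two template spans are combined into one continuous
template-oriented sequence. Overlapping columns (v of them) are proportionally
truncated: round(v·L1/(L1+L2)) columns come off the 3′ end of read 1's span
(round half up, so an odd remainder is taken from read 1) and the rest off the
5′ end of read 2's span; aligner gaps are then removed and the parts
concatenated. Pairs whose spans are out of order (read 2 entirely 5′ of
read 1) are rejected as `discordant`. The merge records the covered template
columns and the gap fraction — gap columns of either direction over all
alignment columns in the merged span.

**Quality filter.** A merge passes if its gap-free length is at least 90% of
the template length and its gap fraction at most 5%; the length criterion is
checked first, so a short, gappy merge counts as `short`. Base qualities are
ignored throughout (the protocol's double conversion and nested PCR leave
length and gap structure as the informative failure modes). Every stage keeps
exact tallies; input pairs = unmatched + passed + short + gappy + discordant
is asserted in the run manifest.

**Pattern calling.** Passed merges are re-aligned to the template — a second
pass, so residual indel placement from merging cannot shift CpG columns — and
scored at each CpG column: C → 1, T → 0. Any other base, a gap, or a CpG
outside the read's span marks the whole read ambiguous; partial patterns are
never emitted because downstream estimation needs a fixed-length sample
space. Declared SNP columns are recorded verbatim alongside the pattern and
never affect pattern identity.

## Frequency estimation and spurious-pattern elimination

Observed patterns are modelled as a multinomial mixture over the true pattern
set. Conditional on true pattern t, sites flip independently with

    p(1 | true 0) = f(1−m) + (1−f)m        p(0 | true 1) = g(1−m) + (1−g)m

where f is the bisulfite non-conversion rate, g the over-conversion rate and
m the per-base substitution rate (defaults 0.005 / 0.005 / 0.003; see below).
The candidate support is the set of observed patterns — at these depths an
entirely unobserved true pattern is negligible, and the restriction keeps the
fit the size of the count table. Mixture weights are maximised by EM,
initialised at the empirical frequencies, stopped when the log-likelihood
changes by less than 1e-8 (at most 10,000 iterations). EM monotonicity is
asserted at every iteration (up to a 1e-8 relative float guard). With all
rates zero the emission matrix is the identity and the estimate equals the
empirical distribution exactly.

Elimination of spurious patterns — those created from true patterns by
conversion/sequencing error — runs in two stages:

1. **Frequency floor.** Patterns with estimated frequency below
   `support_cut` (default 10/n_reads) are removed and the rest renormalised,
   iterating to a fixed point.
2. **Profile likelihood-ratio test.** A floor alone is insufficient: mixture
   weights live on the simplex boundary, and sampling noise leaves one-flip
   neighbours of dominant epialleles with small *positive* ML weight — at
   n = 20,000 and default error rates typically 5×10⁻⁴–10⁻³, i.e. above any
   floor one would sensibly set. Each surviving pattern below 5% is therefore
   tested by refitting the mixture without it; the pattern is kept only if
   twice the log-likelihood drop exceeds a BIC penalty, ln(n_reads).
   Elimination is backward, weakest pattern first, refitting after every
   removal. The 5% ceiling merely skips tests that cannot fail at realistic
   depths. Setting `lrt_penalty=0` disables the stage and yields the pure
   ML-plus-floor estimate (used when comparing against the brute-force
   optimizer oracle).

Error rates are user-supplied (or known to the simulator); joint estimation
of rates and frequencies is deliberately out of scope. Reporting cutoffs (1%
and 5% by default) are applied *after* estimation, on estimated frequencies,
and do not renormalise — retained frequencies keep their estimated values.

## Cross-condition comparisons

Pattern identity across samples is bit-string equality. Venn-style region
counts over 2–5 condition sets assign each pattern to exactly one region (the
subset of conditions containing it), so regions partition the union. Pooled
2-way comparisons (e.g. same-age nurses vs foragers, young vs old) apply the
frequency cutoff within each member library first and then take the union per
group; an alternative mode (`mode="reestimate"`) pools raw counts,
re-estimates, then cuts. Cumulative comparisons sum per-amplicon counts. The
overall methylation level of a library is the mean over CpGs of the per-CpG
combined levels (frequency-weighted column means of the pattern matrix).

## Synthetic data generator

The generator emulates the study design so every stage is testable without
raw data: three amplicons of 551/405/401 bp with 10/15/10 CpGs (CpGs kept out
of the primer zones, as primers are designed CpG-free); five condition
libraries; per condition a mixture of k distinct epiallele patterns (default
k = 8) with symmetric-Dirichlet frequencies (concentration 2.0, giving a few
dominant patterns and a skewed tail, consistent with 80–90% of molecules
falling on at most a dozen patterns); 2×300 nt paired reads carrying the
33-nt primer oligo (unconverted, as sequenced) at their 5′ ends. Molecules
are converted with per-site non-conversion f and over-conversion g, non-CpG
Cs escape conversion at rate 0.002, and each read independently receives
substitutions (0.003/base) and indels (0.0005/base). These magnitudes are
plausible for a double-converted MiSeq library; they are design choices of
this package, exposed as parameters. Base qualities are written as constant
'I' and ignored. All randomness flows from one integer seed through a single
PCG64 stream in a fixed draw order, so identical arguments give
byte-identical FASTQ.

What the generator does **not** model: PCR duplicates and chimeras,
quality-score error profiles (errors are uniform along the read),
demultiplexing/index effects, genotype-linked epialleles (patterns are drawn
independently of any SNP), and condition correlation (each condition's
mixture is drawn independently, so cross-condition pattern sharing in
synthetic runs is near zero). Passing tests therefore demonstrate the
pipeline's correctness and the estimator's calibration under the stated
error model — not robustness to duplicate-driven frequency distortion or to
mis-specified error rates.

## Problem sizes and numerical choices

The test suite validates the zero-error identity end to end at 5 conditions ×
10,000 pairs per amplicon across the full three-amplicon panel, and
error-model recovery at 20 replicates of 20,000 pairs on the 401-bp amplicon;
the acceptance script runs a five-condition study at 2,000 pairs per amplicon
per condition plus a 5×5,000-pair recovery study — sizes chosen to exercise
ultra-deep behaviour (spurious patterns appear and must be eliminated) while
remaining desk-scale. Alignment uses int32 scores with a −2³⁰ sentinel;
EM guards log(0) with the smallest positive float and treats a reduced
support that cannot explain an observed pattern as log-likelihood −∞ (the
pattern is then never eliminated by the LRT). Proportional truncation uses
round-half-up; degenerate span containment clamps the truncation to the
available columns.

## Known limitations

- Error rates must be supplied; the estimator does not learn f/g/m from
  non-CpG cytosines (a natural extension) and miscalibrated rates bias the
  eliminated set.
- Exact primer matching discards every pair with a single error in the 30-nt
  window; at depths of 10⁴–10⁵ this costs coverage, not correctness.
- Patterns supported only by unobserved true epialleles are invisible by
  construction of the observed-support EM.
- The banded aligner assumes primer-anchored register; structural variants
  inside an amplicon would need the full-matrix path (it falls back
  automatically on poor scores, at a throughput cost).
- 2–5-way region counting is exact but the 4/5-way figures are bar charts of
  region counts, not area-proportional diagrams.
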