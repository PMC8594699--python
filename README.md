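# amplimeth

Methylation-pattern (epiallele) analysis of **ultra-deep amplicon bisulfite
sequencing**: from paired FASTQ reads to per-molecule CpG methylation
patterns, error-corrected pattern frequency distributions, and
cross-condition pattern-set comparisons.

## The problem

Organs like the insect brain mix many cell types, so low-depth whole-genome
bisulfite sequencing averages away the cell-type-specific methylation signal.
An alternative design sequences a few long nested-PCR amplicons (≈400–550 bp,
10–15 CpGs each) to depths of 10⁴–10⁵ read pairs per amplicon and condition.
At that depth each sequenced molecule yields an *epihaplotype* — the ordered
binary vector **p ∈ {0,1}ᴶ** of its CpG states — and a condition is
characterised by the frequency distribution θ over those patterns, typically
dominated by a handful of epialleles plus a tail of rare variants.

Two technical obstacles stand between raw reads and θ:

1. **Read processing.** Pairs must be selected by exact nested-primer match,
   aligned to an in-silico bisulfite-converted template with asymmetric
   scoring (read T over template C is a match), merged with proportional
   truncation of the overlap, and length/gap filtered (≥90% of template,
   ≤5% gap columns).
2. **Spurious patterns.** Bisulfite non-conversion (rate *f*), over-conversion
   (*g*) and sequencing substitutions (*m*) turn a true pattern into one-flip
   neighbours, so raw pattern counts overstate diversity. amplimeth models
   observations as a multinomial mixture with per-site flip probabilities
   `p(1|0) = f(1−m)+(1−f)m`, `p(0|1) = g(1−m)+(1−g)m`, fits θ by EM over the
   observed-pattern support, and eliminates spurious patterns with a
   frequency floor (10/n reads) plus a profile likelihood-ratio test against
   a BIC penalty. See `docs/methods.md` for the full model.

A synthetic-data generator reproduces the study geometry (amplicons of
551/405/401 bp with 10/15/10 CpGs, five conditions, 2×300 reads, realistic
error rates) with exact truth tables, so the whole pipeline is testable
without any sequencing download.

## Worked example

Simulate a two-condition study (2,000 pairs per amplicon per condition) and
run the full pipeline:

```
$ amplimeth simulate --out study --seed 7 --n-pairs 2000 --conditions 2 --k 6
simulated 2 conditions x 3 amplicons under study
$ amplimeth run --panel study/panel.toml --samples study/samples.tsv --out study/results
run complete: study/results/manifest.json
```

`study/results/distributions.tsv` holds the error-corrected pattern
frequencies; for the 551-bp amplicon in condition 1:

```
amplicon  sample  pattern     est_frequency  observed_count
amp551    cond1   1100000111  0.32610093     484
amp551    cond1   0111100010  0.22272144     327
amp551    cond1   1100001111  0.16856681     250
amp551    cond1   1101001111  0.13311529     193
amp551    cond1   0000001100  0.09563538     144
amp551    cond1   1110101111  0.05386015     81
```

All six simulated epialleles are recovered (truth for this seed: 0.3347,
0.2180, 0.1591, …) and none of the 37 error-derived patterns in the raw
count table (43 observed patterns in total) survives elimination. `call_summary.tsv` shows the per-stage
bookkeeping (e.g. 1,589 merged pairs → 1,558 called + 31 ambiguous), and
`venn_cutoff0.01.tsv` counts patterns unique to and shared between
conditions at the 1% reporting cutoff:

```
amplicon  region        count
amp551    cond1         5
amp551    cond2         5
amp551    cond1&cond2   1
```

`amplimeth report --run-dir study/results` renders the pattern heat-grids
(rows = patterns, most frequent on top; lower panel = per-CpG combined
levels; read count annotated) and the Venn figures, all drawn from the
exported tables. `manifest.json` records counts at every filter stage and
the conservation identity `input = unmatched + passed + short + gappy +
discordant`.

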