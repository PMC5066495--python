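# Methods

## The scan statistic

At every biallelic SNP the per-bulk SNP-index is the fraction of reads
carrying the ALT allele; Δ(SNP-index) is the B-efficient bulk's index
minus the B-inefficient bulk's. Sites are filtered before windowing:

| filter | default | rationale |
|---|---|---|
| per-bulk depth | ≥ 7 reads | indices from fewer reads are too noisy (standard QTL-seq practice) |
| low index in both bulks | < 0.3, on | a site ALT-poor in *both* bulks is a likely alignment artefact, not a segregating marker |
| parent concordance | opposite homozygotes | a DH-population marker must separate the parents; applied only when parent columns are present |

Windows are 1 Mb wide, advanced in 10-kb steps, anchored at position 1,
with trailing partial windows kept. The window mean is the arithmetic
mean of Δ over non-missing sites inside the window; windows with fewer
than 10 contributing SNPs are treated as missing. Missing per-site Δ
values (zero depth) are excluded, never imputed.

## Null band for the DH design

At a marker unlinked to the trait, each bulk of *n* = 22 DH lines
carries the ALT allele in *k* ~ Binomial(n, ½) lines (DH lines are
fully homozygous, so there is no heterozygote class), the bulk allele
frequency is *k/n*, and ALT reads are Binomial(depth, *k/n*). The band
is the equal-tail interval of Δ between two independent such bulks,
computed by exact enumeration of the (n+1)×(depth+1) outcome lattice
per bulk followed by cross-correlation of the two index distributions.
The lower and upper bounds are computed from their own tails, so the
symmetry of the band is a checkable outcome. A Monte-Carlo mode
estimates the same functional from sampled draws binned on the same
Δ lattice; with 10⁵ draws it reproduces the exact band to the lattice
resolution. Each window is compared against the band at its
representative depth, the median over contributing sites of the mean
per-bulk depth.

## Interval calling and its false-positive control

A window is significant when its mean lies outside the band; runs of at
least 5 consecutive same-sign significant windows merge into one
interval. Two facts shape the defaults:

* adjacent windows share 99% of their sites, so a genuine locus yields
  runs of dozens to hundreds of windows and the 5-window minimum only
  removes singletons;
* the window mean averages away *read* noise but not *line-sampling*
  noise: the true bulk-frequency difference at an unlinked locus has
  SD ≈ √(2·0.25/22) ≈ 0.15 and is strongly autocorrelated along a
  chromosome, so whole linkage blocks occasionally drift beyond the
  95% single-site band. On a no-QTL genome a single excursion can
  cover a third of all windows without indicating any locus.

For that reason interval calling defaults to the 99% band
(`ci_level = 0.99`), which requires an 11-line imbalance between two
random 22-line bulks; across 20 simulated null genomes this yields
zero called intervals, while a fully selected planted locus
(|Δ| → 1) exceeds the band by a wide margin. The 95% band remains
available for exploratory scans.

## Sign convention and allele encoding

The B-efficient parent's allele is encoded as the VCF ALT allele
throughout the simulator (parent samples are emitted as fixed 0/0 and
1/1 homozygotes). With Δ = index(BE bulk) − index(BinE bulk) this makes
the sign directly interpretable: a locus whose trait-raising allele
comes from the B-efficient parent enriches the BE bulk for ALT and
scans positive; one raised by the B-inefficient parent scans negative.
Swapping the two bulk columns negates every Δ and flips every
interval's contributing parent — an identity the tests assert exactly.

## The synthetic study

The generator emulates the study design the package targets:

| parameter | default | meaning |
|---|---|---|
| `n_lines` | 190 | DH population size |
| `bulk_size` | 22 | lines per phenotypic-extreme bulk |
| `parent_depth` / `bulk_depth` | 18 / 45 | mean Poisson sequencing depth per site |
| `trait_cv` | 0.61 | coefficient of variation of low-B dry biomass |
| `trait_range` | 0.0085–0.24 g | truncation range of the trait |
| `cm_per_mb` | 2.0 | genetic-map density (Haldane, no interference) |
| `marker_spacing` | 10 kb | simulated SNP marker spacing |

Lines are single recombinant gametes of the F1, chromosome-doubled:
crossover counts are Poisson with mean equal to the chromosome's
genetic length in Morgans, positions uniform, no interference. The
low-B biomass trait is (baseline + planted additive effects) times a
mean-one log-normal noise factor; the noise variance is chosen so the
realized trait CV matches `trait_cv` after accounting for the variance
the planted loci already contribute (when the genetic variance alone
exceeds the target, no noise is added and the CV exceeds the target —
the intended "effect ≫ noise" regime for recovery experiments).
Values are truncated to `trait_range`; with the default parameters
truncation affects well under 1% of lines. High-B biomass is drawn
near the top of the range independent of the planted low-B loci, and
the B-efficiency coefficient (BEC) is the low/high ratio. Bulks are
the top and bottom `bulk_size` lines by low-B biomass, ordered with
line-id as the deterministic tie-break (the low bulk takes the lowest
ids among ties, the high bulk the highest, so tied populations still
yield disjoint bulks). Deficiency symptoms, which the real bulking
also consulted qualitatively, are not modelled — no formula exists
for them.

Expression tables are simulated per gene × tissue (shoot, root) with 3
replicates per genotype drawn log-normally around a shared gene-level
baseline; planted candidates receive a fold-change (default 8) in
their configured tissue and direction. The p-value is a two-sided
moderated two-sample test on log abundances with the within-group
variance pooled across all genes of a tissue — the standard remedy for
3-replicate designs (full-shrinkage limma-style); with genuinely
per-gene noise scales a per-gene variance estimate would be
preferable. Under the null the p-values are exactly calibrated, which
the suite verifies. FDR is Benjamini–Hochberg within tissue
(delegated to statsmodels and cross-checked against an independent
step-up implementation). The real study's expression profiling had one
library per sample; replicates (and hence test-based p-values) are a
deliberate divergence of the simulator.

What the simulator does **not** emulate: read-level errors, mapping
bias, multi-allelic sites, InDel segregation in the bulks (InDels are
exercised only through toy fixtures in the variant-landscape code),
segregation distortion, and residual heterozygosity. Passing recovery
tests therefore demonstrate correctness of the statistics under clean
sampling assumptions, not robustness to alignment artefacts in real
re-sequencing data.

## Variant-landscape conventions

* Transitions are the unordered pairs A/G and C/T; the other four
  pairs are transversions. Ratios are reported to one decimal,
  percentages to one decimal.
* InDel length is |len(ref) − len(alt)|.
* Feature precedence is genic > 2-kb promoter (strand-aware, upstream
  of the TSS) > 1-kb downstream (strand-aware) > intergenic; a
  position inside any gene is genic regardless of neighbouring genes'
  flanks, and overlapping flanks resolve to the nearer gene, then by
  gene id.
* Coding effects splice the CDS strand-aware, substitute the base and
  translate the affected codon with the standard code; the suite
  checks every call against whole-protein translation.
* π is SNP count divided by assembled chromosome length (SNPs per
  nucleotide), not a sample-heterozygosity estimator.
* Coordinates are 1-based inclusive externally (VCF, GFF3, interval
  TSVs); BED output is 0-based half-open.

## Experiment scales

The seeded experiments (`bulkscan.experiments`) use two 8-Mb
chromosomes with markers every 10 kb — a desk-scale genome on which a
full study simulates and scans in under a second, allowing 20-replicate
null and recovery batches in a few seconds while preserving the study's
population design (190 lines, bulks of 22, 45×/18× depths). At this
scale an 8-Mb chromosome spans 16 cM, so a fully selected locus drags
its whole linkage block outside the band and called intervals span the
chromosome; recovery is judged by containment of the planted position
and correctness of the sign.

## Known limitations

* The null band models an unlinked marker; it is not a genome-wide
  error rate. The run-length requirement plus the 99% level provide
  the practical genome-wide control, as quantified above.
* `scan` infers chromosome lengths from the last marker position when
  no lengths are supplied, truncating any marker-free chromosome tail.
* Multi-allelic VCF records are skipped (with a warning) or naively
  split; allele-depth semantics of upstream callers may differ.
* Candidate nomination inherits every upstream threshold; the funnel
  reports counts at each stage so sensitivity to thresholds is visible
  in the manifest.
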