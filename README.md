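# ggaasat

Genome-wide discovery of GGAA-microsatellites and analysis of their role as
ETS-fusion transcription-factor response elements.

## The problem

ETS-family transcription factors bind DNA at a GGAA core motif. In Ewing
sarcoma, the EWS/FLI fusion protein additionally gains the ability to bind
*microsatellites* — tandem arrays of the GGAA motif — and uses them as
response elements to activate and repress thousands of target genes. Asking
where these elements are, how long they must be to be functional, and how
their length and gene distance relate to binding strength and target-gene
regulation requires a pipeline that can:

1. scan a genome on both strands for GGAA (and its reverse-strand mirror
   TTCC) and chain motif occurrences into **repeat regions** — maximal
   clusters in which adjacent motifs are separated by at most 20 non-motif
   nucleotides, starting and ending with a motif;
2. classify regions as *pure* (one strand) or *mixed* (both strands), split
   mixed regions into same-strand clusters, and compute per-region
   statistics: total motifs *t*, the longest run of directly adjacent
   same-strand motifs *c* (`max_consecutive`), and motif density
   *d* = 4·*t* / length × 100%;
3. call **microsatellites** as regions with *c* ≥ 3 and annotate each with
   its nearest gene (midpoint-to-TSS distance, strand-agnostic), splitting
   them into *promoter-like* (≤ 5 kb) and *enhancer-like* (> 5 kb);
4. test whether microsatellites overlap binding peaks more than chance with
   a universe-resampling permutation test (z = (obs − mean₀)/sd₀, empirical
   p with the +1 Monte-Carlo correction), a uniform-relocation null, and a
   shifted-z profile probing positional specificity;
5. link each peak to its summit-nearest microsatellite and compute Spearman
   correlations (plus tricube LOESS trends with 95% bands) between log₂
   fold-enrichment, |log₂ fold-change| of the nearest gene, and the length
   measures *c*, *t*, *d* — stratified into the four
   {promoter, enhancer} × {activated, repressed} quadrants.

The package implements every stage as a tested library
(`src/ggaasat/`), provides a synthetic-data generator that emulates the
statistical structure such a study assumes (planted repeat classes, a noisy
increasing binding model with a plateau, length-dependent activation at
close range, length-independent repression) with a machine-readable truth
table, and drives the full analysis through numbered scripts under
`analysis/` or the `ggaasat` command-line interface.

## Worked example

Generate the standard synthetic study (4 × 12.5 Mb chromosomes, 200 planted
microsatellites per consecutive-motif class 3–20 plus heavy class-1/2
clutter, seed 1), then run the analysis:

```bash
python analysis/01_simulate.py
python analysis/02_scan_repeat_regions.py
python analysis/03_annotate_nearest_genes.py
python analysis/04_peak_overlap_permutation.py
python analysis/05_binding_expression_correlation.py
```

The scan recovers 45,260 repeat regions, 86% of them single-motif clutter,
3,700 microsatellites (*c* ≥ 3). The permutation stage prints

```
resample   observed= 3,097  null mean=   329.8 sd= 16.50  z=   167.7  p=0.000999
randomize  observed= 3,097  null mean=    88.3 sd=  9.55  z=   315.1  p=0.000999
shifted-z profile peaks at offset 0 bp (z=165.3)
```

— the 3,097 peak-overlapping microsatellites are far beyond both nulls
(p = 1/1001, the floor at 1,000 permutations), and the z-score collapses as
soon as the regions are translated, so the association is positional. The
correlation stage prints the four-quadrant summary:

```
  promoter_like:activated      n=  329  binding r=  0.81  expression r=  0.32
  enhancer_like:activated      n=1,210  binding r=  0.78  expression r= -0.04
  promoter_like:repressed      n=  217  binding r=  0.81  expression r= -0.01
  enhancer_like:repressed      n=  971  binding r=  0.82  expression r= -0.02
```

Binding enrichment tracks microsatellite length in every quadrant; gene
expression tracks length only for promoter-like microsatellites of
activated genes — repression shows no length response anywhere, matching
the planted regulatory structure.

Real data drop in the same way: `ggaasat run-all --genome hg19.fa --peaks
peaks.narrowPeak --genes genes.tsv --de de.tsv` accepts FASTA, ENCODE
narrowPeak/BED6, and TSV gene/differential-expression tables (see
`ggaasat --help` for the `scan`, `annotate`, `permtest`, `associate` and
`simulate` subcommands and the `--max-gap`, `--min-consecutive`,
`--range-threshold`, `--motif`, `--flip-lfc` knobs).

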