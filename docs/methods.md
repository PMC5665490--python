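# Methods

## Repeat-region model

A *motif occurrence* is a 4-bp window equal to GGAA (forward strand) or
TTCC (reverse strand, scanned on the forward sequence — the reverse strand
is never materialized). A *repeat region* is a maximal chain of occurrences,
both strands pooled, in which each adjacent pair is separated by a gap of at
most `max_gap` non-motif nucleotides; the region starts and ends exactly at
motif boundaries. Two readings of the gap rule are possible ("no more than
20 insertions" vs "separated by at least 20 bp"); we merge at gap ≤ 20 and
split at gap ≥ 21, and expose `max_gap` as a knob. Initial chains require at
least two motifs; isolated single occurrences are discarded at this stage.

Regions whose motifs all lie on one strand are *pure*; regions containing
both GGAA and TTCC are *mixed*. Mixed regions are re-processed by splitting
them into maximal same-strand positional runs, each becoming a pure region
with recomputed bounds and statistics. The degenerate mixed region of
exactly one motif per strand is discarded entirely. Single-motif fragments
produced by splitting larger mixed regions are retained — this is the only
way a 1-motif region can exist, and it is what makes the large "1 motif"
class in genome-wide summaries reachable.

Per-region statistics: `total_motifs` t; `max_consecutive` c, the longest
run of directly adjacent (zero-gap) same-strand motifs; `density`
d = 4t/length × 100 (d ∈ (0, 100], with d = 100 iff all motifs are mutually
adjacent); length in bp. Consecutive-motif *classes* used for profiles and
comparisons are the value of c with everything ≥ 6 pooled. A
*microsatellite* is a region with c ≥ 3, the minimal length at which these
elements act as ETS-fusion response elements; the threshold is the
`min_consecutive` parameter. Soft-masked (lowercase) sequence is scanned
like ordinary sequence by default, since masking status is part of the
reference rather than of the biology being tested; `--exclude-softmask`
drops occurrences overlapping masked intervals. Scanning for a different
4-mer (e.g. a TTCC-centric analysis) is the same code path via `--motif`.

## Gene annotation

Distance is measured from the region midpoint `(start+end)//2` to the gene
TSS, regardless of gene strand; ties between equidistant genes resolve to
the lexicographically smaller gene id so annotation is deterministic.
Pseudo-genes are excluded at load time. Promoter-like means distance ≤ 5 kb
(inclusive); enhancer-like otherwise. Feature labels additionally use the
strand-aware signed offset (upstream = before the TSS in transcription
direction) with bins ≤1 kb / 1–2 kb / 2–3 kb upstream, ≤3 kb downstream,
gene body when interval data is supplied, and distal otherwise; this is a
deliberate simplification of richer annotation taxonomies.

Distance comparisons between consecutive-motif classes use a Welch
(unequal-variance) two-sample t-test on log10(distance+1) against the
pooled class-{1,2} reference; raw distances are heavy-tailed, so the log
scale is the default and raw mode is available by flag. Medians are
reported on the raw scale.

## Overlap permutation tests

Overlap is ≥ 1 bp under half-open interval semantics, and a query region
counts once no matter how many subject regions it touches. The primary null
resamples |query| regions uniformly without replacement from a fixed
universe (all repeat regions, of which microsatellites are a subset), which
preserves the internal structure of repeat regions. Because every draw is a
subset of the universe, the per-region overlap indicator is precomputed
once and each permutation is a subset sum — identical in distribution to
re-counting overlaps per draw, and what makes 500-replicate calibration
studies cheap. The empirical p uses the +1 Monte-Carlo correction,
p = (1 + #{null ≥ obs})/(n_perm + 1), so p ∈ [1/(n_perm+1), 1] and is never
zero; z = (obs − mean₀)/sd₀ with the sample standard deviation, reported as
an undefined sentinel (None) when the null is degenerate rather than
propagating NaN. Default n_perm = 1,000.

The second null relocates each query region independently and
length-preservingly, uniform over all valid placements in the mappable
space (the non-N intervals of the genome by default), across chromosomes.
The shifted-z profile translates the query by each offset of a grid
(which must include 0), clips to chromosome bounds, drops and counts
regions clipped away entirely (wrapping would fabricate juxtapositions),
and recomputes the resampling z with the same seed schedule, so the offset-0
entry reproduces the unshifted statistic exactly. The default grid spans
±50 median region spans in 21 steps; the grid is configurable because the
informative range depends on the data's characteristic spacing.

## Association and correlation

Each peak is assigned the microsatellite whose midpoint is nearest its
summit; midpoint ties go to the smaller start coordinate. A microsatellite
bound by several peaks is represented once by its maximal-fold-enrichment
peak, because bound microsatellites are counted as a set. Microsatellites
with more than 20 consecutive motifs are excluded from length analyses
(too few exist for informative statistics); the cap is configurable.
Regulation calls use the differential-expression table at FDR ≤ 5%:
activated means expression is higher with the fusion present (log2fc > 0
under the table's required orientation; `--flip-lfc` handles the opposite
convention), repressed lower, unchanged otherwise.

Correlations are Spearman's rank correlation (midrank ties, two-sided p by
the t-approximation), computed on log₂ fold-enrichment for the binding axis
and |log₂ fold-change| within a regulation class for the expression axis
(magnitude of the response; a signed mode is available by flag, and rank
correlation is invariant to the monotone log transforms). The null band
quoted alongside a correlation is the large-sample 95% band for
independence, 1.96/√(n−1). Trend fits are tricube-weighted local polynomial
regression (LOESS), default span 0.75 and degree 2, with pointwise 95%
bands of fitted ± 1.96 × the standard error of the local weighted
least-squares estimate; degenerate local windows (all-equal x) fall back to
a weighted mean. The LOESS implementation is local and in-package because
the degree-2 fit with t-based bands is part of the analysis contract.

## Synthetic data

The generator emulates the downstream products of a repeat-element binding
study, not reads: a genome FASTA, a gene TSV, a narrowPeak file and a
differential-expression TSV, plus a truth table with one row per expected
post-split region.

*Genome.* Each planted region is composed of motif runs — a main run of c
adjacent motifs defining its class, extra shorter runs (Poisson-distributed,
never longer than c), and for a `mixed_fraction` of regions one
opposite-strand singleton — separated by 1–20 bp motif-free spacers built
from a C/T alternation that provably cannot create or extend motifs at run
junctions. Regions are placed one per uniform slot across each chromosome,
which spreads them genome-wide and guarantees adjacent planted elements can
never chain. Background is i.i.d. uniform A/C/G/T; incidental GGAA/TTCC
windows are destroyed only inside a 24-bp buffer around planted regions (so
planted truth is exact) and kept elsewhere, recorded as unplanted truth by
a scan of the emitted sequence — the scanner is therefore always exercised
against realistic clutter. The default scenario is 4 chromosomes × 12.5 Mb
with 200 regions per class 3–20 and 3,000 class-1/2 regions, sized so that
microsatellites sit ~14 kb apart and the promoter/enhancer split is
meaningful at a 5-kb threshold.

*Genes.* A fraction (default 0.15) of planted microsatellites receive a
dedicated promoter-linked gene with TSS within ±4 kb of the fragment
midpoint; the remaining genes (700 total by default) are uniform, sparse
enough that unlinked microsatellites are predominantly enhancer-like. A
small fraction are flagged pseudo-genes to exercise the load-time filter.

*Peaks.* Each planted microsatellite is bound with probability
π(c) = 0.98/(1+e^{−(c−5)/1.5}) — increasing in length, ~0.2 at c = 3 —
and emits a peak with summit jittered N(0, 20 bp) around the midpoint and
fold-enrichment a + b·min(c, plateau) + N(0, σ) with defaults a = 2,
b = 0.35, plateau class 16 (echoing the observed saturation of binding
with length) and σ = 1, floored away from zero. 150 uniform noise peaks are
added.

*Expression.* The nearest gene of each bound microsatellite is drawn
activated or repressed with distance-class-specific probabilities.
Activated genes at close range get log2fc ~ N(μ_act·min(c, plateau)/plateau,
0.6) — length-dependent activation; distal activated genes get a
length-independent mean; repression is N(−μ_rep, 0.6) everywhere,
independent of length. Regulated genes get FDR ≪ 0.05, all others
fdr ~ U(0.05, 1) with a small centred fold-change. This is exactly the
regulatory asymmetry the quadrant analysis is designed to detect, so
end-to-end recovery of the pattern is a meaningful check of every stage.

What the generator does **not** emulate: read-level noise, GC and chromatin
structure, polymorphic repeat lengths, correlated peak widths, or any
linkage between clutter regions and genes. Passing tests therefore
demonstrate the correctness and calibration of the pipeline's machinery on
data with the assumed statistical structure, not the biological conclusions
on a real genome.

## Numerical and design choices

- Coordinates are 0-based half-open throughout; GTF-style input is
  converted on ingestion (TSS = start for "+", end−1 for "−").
- BED output is sorted (chrom, start, end, strand) with densities fixed to
  4 decimals, so identical inputs give bit-identical files.
- All pipeline randomness derives from one seed fanned out per stage by
  hashing the stage name (blake2s, reduced below 2³¹), so stages are
  individually reproducible.
- narrowPeak summits use start + column-10 offset, falling back to the
  interval midpoint (with a warning) for offset −1; BED6 summits are floor
  midpoints and scores are rescaled to fold-enrichment by /100, documented
  here because BED6 carries no enrichment column.
- Degenerate cases: empty sequences scan to empty lists; a region
  chromosome with no genes yields an infinite-distance sentinel classed
  enhancer-like with a warning; zero-spread permutation nulls report z as
  None while p remains valid.
- Problem sizes in the test suite and acceptance script (2-kb oracle
  sequences, 400-region calibration universes, the 50-Mb default scenario)
  were chosen as the smallest scales at which each statistical property is
  cleanly measurable.

## Known limitations

- The feature taxonomy is a six-label simplification; exon/intron-level
  annotation is out of scope.
- The relocation null places regions independently, so it does not preserve
  inter-region spacing; GC- or chromatin-matched nulls are not provided.
- LOESS bands are pointwise t-approximations, not simultaneous bands, and
  use a locally estimated residual variance.
- Genome-scale headline counts from a real reference require scanning that
  reference; the package applies unchanged (`ggaasat scan --genome ...`)
  but no external data is bundled.
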