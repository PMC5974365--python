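# Methods

This note records the models, parameter choices and numerical policies
behind `epidiff`, and what the synthetic test bed does and does not
demonstrate about real data.

## Coordinates and methylation levels

All in-memory intervals are 0-based half-open; GFF3 (1-based inclusive)
and cytosine reports (1-based positions) are converted at the I/O
boundary only.  A cytosine site enters analysis when it carries at
least `min_coverage = 5` reads.  Two notions of "methylation level"
coexist deliberately:

* the **site mean** — unweighted mean of per-site levels — is the
  default for genome-wide context means, matching common WGBS
  reporting; a read-weighted variant sits behind `weighted=True`;
* the **pooled level** — summed methylated reads over summed reads —
  is used wherever sites are aggregated into small units (metagene
  bins, 200 bp DMR windows, genic regions), because per-site levels at
  ~20× coverage are too noisy to average meaningfully in small bins.

Strand handling: the cytosine-report dialect is strand-resolved and the
package keeps the two strands of a symmetric CG pair as separate
records by default; `merge_cg_strands=True` sums the pair into one
site.  Whether to combine strands is a genuine free choice in this kind
of analysis; both behaviours are exposed and the default mirrors the
input dialect.

## Metagene profiles

Features are scaled to 20 body bins between their start and end, with
ten 100 bp flank bins on each side (1 kb flanks); minus-strand features
are mirrored so bin 0 is always the far upstream flank.  Bins pool
counts rather than averaging per-site levels.  Features shorter than
the bin count (20 bp) are excluded and logged.

## DMR calling

Synteny blocks are supplied as equal-length coordinate pairs; the
colinear 1:1 base mapping is a declared simplification (real alignments
with indels are out of scope) and the synthetic generator emits
gap-free blocks.  Each block is tiled into `window_size = 200` bp
windows at `window_step = 100` bp; a window is tested only when both
species have at least `min_sites = 4` covered CG sites in it (untested
windows are reported separately, and do not enter the FDR).

The per-window test is a two-sided exact binomial test of species A's
pooled methylated count.  Three reference formulations are provided:

* `binom_pooled` (default): success probability = the level pooled
  over **both** species.  Under the null this is conservative (the
  tested deviation is about half the two-sample difference), which
  keeps the BH-adjusted false discovery rate controlled even though
  the reference level is itself estimated.
* `binom_vs_other`: success probability = species B's observed level.
  This most literal two-sample reduction ignores the sampling noise in
  B; with equal coverage its null statistic has roughly twice the
  nominal variance, and simulation shows the realized FDR after BH can
  reach ~0.35 where 0.05 is intended.  It is kept for sensitivity
  analysis, not as the default.
* `fisher`: Fisher's exact test on the 2×2 count table, a fully
  calibrated alternative.

A reference level of exactly 0 or 1 is clamped to
`[1/(2n), 1 − 1/(2n)]` to keep the binomial test defined; the decision
is logged.  P-values are corrected by Benjamini–Hochberg (statsmodels),
windows with q < 0.05 and a defined direction are kept, and
overlapping **or book-ended** windows of the same direction merge into
maximal DMRs (with a 100 bp step and 200 bp windows, true overlap is
the expected case anyway).  Opposite-direction overlaps are never
merged; both DMRs are emitted and the overlap logged.  Classification
uses species-A annotations with precedence genic (gene body ± 1 kb) >
repeat > intergenic.  No minimum methylation difference is required by
default (configurable).

## siRNA clusters

Collapsed reads (identical sequences with a copy count) are clustered
by single linkage: a read joins the current run when its start lies
strictly less than `cluster_gap = 100` bp after the furthest end seen
so far on that contig, strand-agnostically.  A raw cluster survives
when its abundance reaches `cluster_min_rpm = 5` reads per million
mapped (denominator supplied by the caller as a library-level count)
and it contains `cluster_min_distinct = 10` distinct sequences —
distinct *sequences*, not positions, matching small-RNA collapsing
practice.  Filtering removes whole clusters and never splits them, so
surviving clusters on one contig are always ≥ 100 bp apart.

Length histograms are copy-weighted over 18–30 nt; the cross-species
comparison is a Pearson chi-squared on the 2×k table with tail bins
pooled inward until every expected count reaches 5.  Note that
copy-weighted counts are clumped (all copies of a collapsed read share
one length), which inflates the chi-squared statistic relative to its
nominal calibration; a distinct-read-weighted comparison (each
collapsed sequence counted once) is the calibrated variant and is what
the acceptance script reports alongside the copy-weighted one.  Region labels use
precedence TE > genic > intergenic.  The methylation contrast compares
pooled CG levels of genic regions (gene body ± 1 kb) that do vs do not
overlap a cluster, by two-sided Mann–Whitney.

## LTR dating

Transitions (A↔G, C↔T) and transversions are counted over aligned
columns, skipping any column with a gap or N in either sequence
(pairwise deletion, keeping elements independent of each other).  The
Kimura 2-parameter distance d = −½ln(1−2P−Q) − ¼ln(1−2Q) is converted
to age = d/(2·rate) with rate = 1.05×10⁻⁹ substitutions/site/year.
Saturated pairs (a log argument ≤ 0) are flagged unestimable and
excluded from age histograms with an explicit count — clamping would
fabricate finite ages.  Input pairs are expected pre-aligned; the
synthetic path emits gap-free pairs, and alignment quality for real
data is the caller's responsibility.

Sampling error matters here: at d ≈ 0.038 the per-element standard
deviation of the age estimate is ≈ 0.9 MY for 10 kb repeats and ≈ 3 MY
for 1 kb repeats, so individual ages scatter accordingly and only batch
means (or histogram modes over sufficiently many elements) are tight.

## Expression links

Flank categories are strand-oriented: TE_TE / TE_non / non_TE /
non_non name (upstream, downstream) TE presence within 1 kb, counting
any ≥ 1 bp overlap; flanks truncate at contig edges.  Expression enters
correlations as log₂(FPKM + 1) (raw scale and Spearman variants are
exposed); genes with no covered CG site in a region are excluded from
that region's correlation rather than imputed as zero.  The binned
report uses a zero-methylation bin plus deciles of the positive levels.

## The synthetic generator

The generator's job is to emit data whose *statistical structure*
matches what the analyses assume, with every planted quantity recorded
in `truth.json`:

* **Genomes** — by default two 5 Mb contigs per species at 50% GC,
  packed without overlap with ~50% gene bp (gamma-distributed lengths,
  mean 1.5 kb) and ~20% TE bp (mean 4 kb).  Species B applies uniform
  point substitutions (default rate 0.03/site, roughly the silent-site
  divergence of congeners separated ~15–20 MY at the fungal rate)
  within equal-length synteny blocks tiling the contigs.
* **CG preservation and a shared baseline** — substitutions neither
  destroy nor create CG dinucleotides by default, so CG sites stay
  coordinate-matched, and the two species then draw their baseline
  per-site CG methylation probabilities from one shared seeded stream.
  Without this, independent draws would create real but unrecorded
  methylation differences and the truth file could not score DMR false
  discoveries; with it, planted windows are the only true CG
  differences.
* **Methylation mixture** — TE cytosines draw CG probabilities from
  Beta(8, 2); most genes and intergenic space from Beta(1, 40); a
  minority class of body-methylated genes (fraction 0.15) from
  Beta(12, 2); CHG/CHH everywhere from Beta(1, 60).  Coverage is
  Poisson(20), methylated counts binomial.  The body-methylated class
  reflects the bimodal gene-level methylation real fungal genomes show
  and is what gives gene bodies enough between-gene variance for a
  detectable methylation–expression correlation: with a single
  low-methylation beta, pooling ~10² sites per gene collapses
  between-gene variation to σ ≈ 0.003 and no correlation could exist.
  Parameters were fixed once from the mixture arithmetic so that
  site-level CG bimodality (fraction < 10% plus fraction > 80%) stays
  ≈ 0.84.
* **Planted DMRs** — 100 windows of 200 bp at step-aligned offsets,
  ≥ 200 bp apart, half hypermethylated in each species (CG
  probabilities 0.8 vs 0.2).  A separate focused benchmark
  (`simulate_dmr_benchmark`) builds 1000 single-window blocks — 100
  planted at 0.8/0.2, 900 null at 0.5 in both species, 8 CG sites per
  window — for sensitivity/FDR scoring.
* **siRNA** — total collapsed copies default to 0.02 per genome bp
  (200k at the default scale) so background density, which controls
  spurious cluster chaining, is scale-invariant; 75% of copies land in
  dense runs (start gaps < 80 bp) over a random 60% of TEs, the rest
  uniformly; lengths peak at 21–25 nt (~79% of mass).
* **Expression** — log₂(FPKM+1) = 5 − 2·(flanking-TE mCG) −
  2·(body mCG) + N(0, 1), floored at zero FPKM.
* **LTR pairs** — a random ancestor evolves into two copies, each for
  d/2 expected substitutions/site under a K2P rate matrix with
  transition/transversion ratio 2 (matrix exponential, per-site
  multinomial draws).

All stages draw from `numpy.random.default_rng` seeded by the run seed
plus a fixed stage index, so a seed reproduces every output byte for
byte.

**What passing tests do and do not show.**  The generator has no indel
variation, no TE families or sequence models, no bisulfite
non-conversion error, no replicate structure, uniform GC, and
independent sites within compartments.  Tests therefore demonstrate
that the estimators and filters are implemented correctly and recover
planted truth under the stated noise models — not that the pipeline's
defaults are optimal for any particular real genome.

## Problem sizes used in tests

The simulator default (2 × 5 Mb per species) is kept for users; the
test suite and the acceptance script exercise the pattern battery at
2 × 1 Mb (≈ 670 genes, ≈ 100 TEs, ≈ 10⁶ cytosines — ample for every
ordering/sign/significance check, all of which are scale-free),
determinism at 2 × 200 kb, the DMR benchmark at 1000 windows × 10
seeds, and LTR recovery with 50 × 10 kb and 10 × 1000 × 1 kb pairs.

## Known limitations

* Synteny blocks are equal-length colinear pairs; indel-containing
  alignments must be resolved upstream.
* One methylome per species: no dispersion modeling across biological
  replicates (none is attempted).
* The binomial DMR test treats pooled counts as independent reads;
  within-window site correlation is not modeled.
* RPM thresholds depend on the caller-supplied mapped-read total;
  nothing validates that choice beyond a consistency check.
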