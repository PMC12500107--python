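# Methods

This note documents the models, numerical choices, and defaults behind
`cutrunkit`, and what its synthetic-data generator does and does not
emulate.

## Percentile-based track normalization

Two coverage tracks of the same antibody sequenced to different effective
depths differ, to first order, by one global multiplicative factor.
Depth/library-size normalization (CPM-style) is dominated by background
bins and is blind to differences in the enriched fraction, so the package
instead equalizes the scale of the *enriched* signal:

1. **Local maxima.** Bin *i* of a binned track is a local maximum iff
   `v[i] > v[i-1]` and `v[i] >= v[i+1]`. The strict-left / non-strict-right
   rule makes the definition deterministic and counts each plateau once, at
   its leftmost bin; chromosome-boundary bins are never maxima. (With a
   non-strict right comparison, the left shoulder of a plateau that later
   rises also qualifies; at 50 bp resolution on count data this is rare and
   harmless, and the rule keeps the definition one line.)
2. **Blacklist.** Spurious alignment pile-ups recur at the same bins across
   unrelated antibodies and IgG, with heights that do not track genuine
   signal. A bin is blacklisted when, in at least a `recurrence` fraction
   of samples (default 1.0 — all samples), it carries an intergenic local
   maximum (bin midpoint outside every gene body) whose height exceeds that
   sample's `height_quantile` of maxima heights (default 0.999). Because
   genuine peaks of different antibodies do not coincide at bin resolution,
   recurrence across a multi-antibody panel is the discriminating filter;
   the height quantile mainly bounds the candidate list. For heavily
   contaminated inputs (artifact counts approaching the 0.1% tail of the
   maxima population) the quantile should be lowered so the candidate
   threshold sits below the artifact heights — recurrence still removes
   genuine peaks.
3. **Scaling.** The factor is the ratio of the 99th percentiles of
   blacklist-excluded maxima heights, reference over target; every bin of
   the target is multiplied by it. Percentiles use linear interpolation on
   the sorted heights (`numpy.percentile` default). Requiring at least 100
   usable maxima per track guards the percentile against tiny inputs.
   Factors are always expressed target→reference; the reference is the
   first sample of each mark in the manifest. Normalization is strictly
   within-mark: different antibodies have genuinely different dynamic
   ranges, and equalizing their percentiles would be meaningless.

Re-estimating the factor after scaling returns 1.0 to ~1e-12 (percentile
interpolation is homogeneous of degree one), and factor(A→B)·factor(B→A)=1
to the same tolerance.

## Interval algebra and locus classes

Coordinates are 0-based half-open throughout (BED convention); "overlap"
means ≥ 1 bp (the bedtools intersect default). Intersection reports maximal
intervals covered by at least one region of each input. Subtraction is
**region-level**: a region of A survives only when it overlaps no region of
B — peak regions are kept or discarded whole, never clipped, which is how
"peaks that did not overlap" classes (PRC1-only loci, H3K4me3-only
promoters) are defined in comparative chromatin analyses. Consensus across
replicates is the iterated intersection. `closest_feature` measures the bp
gap to gene bodies (0 for any overlap, and also for exact adjacency in
half-open coordinates), with ties broken by smaller gene start and then
gene id; summits are labelled intragenic by their midpoint.

## Signal matrices and length-scaled abundance

`signal_matrix` mirrors the two standard aggregate-heatmap layouts:
*reference-point* rows are raw bins spanning ±`flank` around an anchor
(region midpoint, or the TSS of a gene), and *scale-regions* rows resample
each body onto `n_bins` equal sub-segments by exact coverage-weighted
averaging (a prefix-integral of the step-function track evaluated at
fractional boundaries), with unscaled flanking bins on each side.
Minus-strand gene rows are reversed so columns read 5′→3′. Windows that run
past a chromosome edge are zero-padded and flagged.

The resampling conserves mass exactly, so the row sum of a flankless
scale-regions matrix — the **length-scaled abundance** — equals
`n_bins ×` the per-base mean signal of the region. This identity (machine
precision) is what makes abundances comparable across regions of different
lengths, and is asserted in the tests. Defaults: `n_bins = 100` bodies,
2 kb flanks for metagenes (the body bin count is a free choice; 100 gives
1% resolution of relative position).

Derived tables: MA values use `M = log2((late+1)/(early+1))` with a
pseudocount of 1 on the abundance scale (regions near zero abundance
otherwise dominate the ratio scale); decile partitions rank ascending with
ties broken by gene id so the partition is total, balanced (sizes differ by
≤ 1) and deterministic; TPM divides counts by summed exon length in kb and
rescales to 1e6 (raw counts in the numerator). For the H3K27me1-vs-
expression comparison, the promoter is the 1 kb upstream of the TSS
(strand-adjusted) and a gene is excluded when any H3K27me3 peak overlaps
the window extending a further 5 kb upstream — a literal reading of
"within 5 kb upstream of the promoter".

## Differential abundance: empirical-Bayes moderated t

Per-region log2 signal (length-scaled abundance or normalized counts, +1
pseudocount) for two conditions with n₁, n₂ replicates is modelled with a
common within-condition variance s²_g on d = n₁+n₂−2 df, and the variances
are shrunk toward a scaled inverse-chi-square prior with df d₀ and scale
s₀²:

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d)
    t_g  = log2FC_g / (s̃_g · sqrt(1/n₁ + 1/n₂)),   df = d₀ + d

(d₀, s₀²) are fitted by moment matching on log s²_g: the mean and variance
of `log s² − ψ(d/2) + log(d/2)` identify s₀² and d₀ through the digamma and
trigamma functions, with the trigamma inverted by Newton iteration. When
the observed spread of log s² does not exceed chi-square sampling noise,
d₀ = ∞ and all variances collapse to the common s₀². At d₀ = 0 the
statistic reduces exactly to the classical pooled-variance t (verified in
tests), and the whole procedure is cross-checked against Bioconductor
limma's `lmFit`/`eBayes` on the same matrix (agreement to ~1e-5 relative).
Degenerate regions (zero variance, zero difference) take t = 0, p = 1 by
convention. P-values are two-sided from the t distribution on d₀+d df;
multiple testing uses Benjamini–Hochberg. The three-class labelling calls
*increased* at adjusted p < α (default 0.05) and fold change ≥ the
threshold (default 1.5×; exposed because a fold-change cut of 1.0 is also
in legitimate use), *decreased* symmetrically, else *unchanged*.

The model is exposed as `DifferentialAbundance(data, design).fit()` →
`DifferentialResults` with `.table`, `.d0`, `.s0_squared`, `.classify()`
and `.summary()`.

## Other statistics

Two-sample Kolmogorov–Smirnov tests use the exact D (sup of the ECDF
difference over pooled points, via scipy) with the asymptotic p-value.
Track correlations are Pearson r over bins outside the blacklist and,
optionally, inside a region mask (e.g. a peak compartment); bins where both
tracks are zero are retained, since shared emptiness is genuine agreement
for genome-wide tracks. PCA variance fractions come from the singular
values of the column-centered samples × features matrix.

## The synthetic-data generator

`simulate_experiment` emulates the statistical structure the analysis
assumes, at a desk scale of 2 chromosomes × 2 Mb with 50 bp bins (80k bins):

* per-bin coverage is Poisson around `background_rate` (default 2
  reads/bin) plus **flat-top** enrichments over peak footprints; flat tops
  (rather than Gaussian bumps) give length-scaled abundance a closed-form
  expectation, so tests have analytic oracles;
* peak heights are lognormal (median 30, log-sd 0.8 — a heavy upper tail
  so the 99th percentile of maxima sits in genuine signal), widths 6–40
  bins; per mark: 300 (H2AK119ub), 200 (H3K27me3), 250 (H3K4me3), 0 (IgG);
* each sample is multiplied by a planted global scale factor, by default
  U[0.9, 1.1] — samples sequenced to closely matched depths;
* 15 shared intergenic artifact spikes of identical absolute height
  (10× the 99th percentile of maxima heights) are added to every antibody
  track at the same bins, *after* depth scaling — they model alignment
  pathologies that do not track genuine signal;
* 60 footprints of the primary mark carry true log2 fold changes
  ~N(0, 1.5) at the late timepoint; an H3K27me1-like mark covers the
  bodies of a known 30% gene subset; genes whose promoters gain the
  primary mark have their expression halved at the late timepoint;
* expression counts are negative-binomial (dispersion 0.3) around
  lognormal gene means;
* the replicate count matrix for differential testing is Gaussian on the
  log2 scale with variances drawn from a scaled inverse-chi-square
  (d₀ = 4, s₀ = 0.4) — exactly the hierarchy the moderated t assumes, so
  its type-I error and FDR are testable, with s₀ = 0.4 reflecting the
  tight replicate agreement of depth-matched CUT&RUN.

Everything is bitwise deterministic under the config seed.

**What passing tests do and do not show.** The generator has no
fragment-length structure, no GC or mappability bias, no spatially
correlated background, no peak-boundary uncertainty (peak sets are the true
footprints), and artifact spikes are single-bin and exactly shared. Tests
therefore demonstrate that the algorithms recover what they are designed to
recover under their own assumptions — calibration and correctness — not
that real tissue data meet those assumptions. In particular, real peak
callers return noisy footprints and real artifacts have width, so the
blacklist recurrence window (±1 bin) and the region-level subtraction
semantics should be revisited before applying the defaults to noisy peak
sets.

## Pipeline conventions

Stages run normalize → classify → quantify → stats. The pipeline's
differential stage uses the merged union of the primary mark's early and
late peak sets as its analysis regions (a consensus across timepoints must
retain regions present at only one timepoint, else the differential classes
are censored). K-S comparisons use replicate-mean normalized tracks. The
run report contains no timestamps and hashes only analysis parameters, so
identical inputs + seed ⇒ byte-identical `report.json`; wall-clock timing
goes to the run log. Percentages in the report are
`round(100 · count / total, 1)`.

Note on the demo: cross-timepoint scaling factors for the primary mark can
deviate from the planted truth by a few percent more than same-condition
pairs, because the planted differential program genuinely shifts the upper
percentile of late-timepoint maxima — the same (small) bias any
enrichment-anchored normalization has when the enriched compartment itself
changes between conditions.

## Problem sizes

Validation experiments run at the desk scale above: 20 simulations for
scaling-factor recovery, 200 randomized 100 kb instances for the interval
oracle, 2000 regions × 4 replicates per condition for moderated-t
calibration and power, 100 random pairs for the K-S oracle. These sizes
give stable statistics (binomial noise on rates ≈ 0.5%) while keeping the
whole suite around a minute of CPU.

## Known limitations

* bedGraph is the on-disk track format (bit-exact text round trips);
  bigwig is supported read-only and only when pyBigWig is installed.
* Peak calling, read alignment, and spike-in (exogenous genome)
  normalization are out of scope; peaks are inputs.
* Only intragenic/intergenic annotation is provided, not a full
  promoter/exon/intron precedence scheme.
* `build_blacklist` assumes several samples spanning unrelated antibodies;
  with replicates of a single antibody, genuine summits can recur and the
  false-positive guarantee weakens.
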