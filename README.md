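# cutrunkit

Comparative analysis of binned CUT&RUN coverage tracks: percentile-based
normalization with artifact blacklisting, interval-algebra classification
of chromatin loci, length-scaled and metagene quantification, and
empirical-Bayes moderated-t differential abundance — plus a synthetic-data
generator with recorded ground truth so every stage is testable without
any sequencing data.

## Who this is for

CUT&RUN maps histone modifications and chromatin factors genome-wide with
low background. Comparing such maps between two conditions — for example,
Polycomb-deposited H2AK119ub and H3K27me3 landscapes at two developmental
timepoints — requires a chain of small but error-prone computational
steps: equalizing tracks sequenced to different depths, excluding
recurrent alignment artifacts, classifying loci by peak overlap (PRC1-only
vs PRC1–PRC2 co-occupied, bivalent vs H3K4me3-only promoters), making
signal comparable across regions of different lengths, and testing
per-region changes with few replicates. `cutrunkit` implements that chain
as a tested library with a thin CLI.

## The core methods

**Percentile normalization.** For two tracks of one antibody, the scaling
factor is the ratio of the 99th percentiles of local-maxima heights,
computed after excluding a blacklist of recurrent extreme intergenic
maxima (shared alignment artifacts):

    factor = P99(reference maxima heights) / P99(target maxima heights)

Every 50 bp bin of the target is multiplied by the factor. This equalizes
the *enriched* signal scale rather than total read count.

**Moderated t.** Per-region log2 signal with per-region variances s²_g on
d residual df is shrunk toward a scaled inverse-chi-square prior (d₀, s₀²)
fitted by moment matching on log s²:

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d)
    t_g  = log2FC_g / (s̃_g·√(1/n₁ + 1/n₂)),  df = d₀ + d

with Benjamini–Hochberg control and a three-class labelling (increased /
decreased / unchanged at adjusted p < 0.05 and fold change ≥ 1.5 by
default). The implementation is cross-checked against Bioconductor limma
in the test suite.

See `docs/methods.md` for the full model descriptions, defaults, and
limitations.

## Worked example

```python
from cutrunkit import (SimulationConfig, simulate_experiment, find_local_maxima,
                       build_blacklist, compute_scaling_factor,
                       DifferentialAbundance, simulate_counts_matrix)

# a synthetic two-timepoint experiment with a planted 1.7x depth difference
cfg = SimulationConfig(seed=1, include_rna=False, include_me1=False,
                       scale_factors={"H2AK119ub_early_rep2": 1 / 1.7})
exp = simulate_experiment(cfg)

maxima = {sid: find_local_maxima(t) for sid, t in exp.tracks.items()}
blacklist = build_blacklist(maxima, exp.genes)
sf = compute_scaling_factor(exp.tracks["H2AK119ub_early_rep1"],
                            exp.tracks["H2AK119ub_early_rep2"], blacklist)
print(f"blacklist: {len(blacklist)} regions; factor {sf.value:.3f} (true 1.700)")

# differential abundance on a simulated replicate matrix (5% true changes)
matrix, truth = simulate_counts_matrix(n_regions=2000, n_per_condition=4,
                                       frac_differential=0.05, log2fc=2.0, seed=1)
res = DifferentialAbundance(matrix, ["early"]*4 + ["late"]*4).fit()
print(res.summary())
```

prints

```
blacklist: 15 regions; factor 1.717 (true 1.700)
Differential abundance (empirical-Bayes moderated t)
====================================================
regions: 2000    samples: 8 (early vs late)
prior df (d0): 4.026    prior variance (s0^2): 0.1595
thresholds: adjusted p < 0.05, fold change >= 1.5
increased: 38 (1.9%)
decreased: 57 (2.9%)
unchanged: 1905
```

All 15 injected artifact bins were recovered (no false positives), the
planted 1.7× depth difference is re-estimated to 1%, the fitted prior df
4.03 recovers the generating value 4, and the 95 regions called at the
default thresholds recover 88 of the 100 planted differential regions
(realized FDR 0.07).

The same flow is available from the shell — `cutrunkit simulate`,
`blacklist`, `normalize`, `classify`, `quantify`, `diff`, `correlate`,
`ks`, `report`, and `demo`. `cutrunkit demo --outdir out --seed 1` runs
the whole pipeline on the default synthetic experiment and writes a
narrated report (`out/demo.txt`) plus a machine-readable
`out/run/report.json` that is byte-identical across runs with the same
seed.

## Layout

- `src/cutrunkit/genome.py` — genomes, regions, binned tracks, gene models
- `src/cutrunkit/io.py` — BED / bedGraph / gene-table / TSV readers-writers
- `src/cutrunkit/intervals.py` — intersect, subtract, consensus, overlap
  fractions, promoter and PRC-locus classification, closest-gene mapping
- `src/cutrunkit/normalize.py` — local maxima, blacklist, percentile scaling,
  spike-in antibody specificity
- `src/cutrunkit/quantify.py` — signal matrices, length-scaled abundance,
  deciles, MA tables, TPM, promoter-class expression
- `src/cutrunkit/stats.py` — K-S, masked Pearson matrices, moderated t
  (`DifferentialAbundance` model / results), BH, PCA
- `src/cutrunkit/simulate.py` — the ground-truth synthetic generator
- `src/cutrunkit/validation.py` — parameter-recovery and calibration
  experiments
- `src/cutrunkit/pipeline.py`, `cli.py` — orchestration and the `cutrunkit`
  command
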