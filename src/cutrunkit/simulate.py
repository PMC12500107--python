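"""Synthetic genomes, tracks, peak sets, gene models and count matrices.

The generator emulates the statistical structure a two-timepoint CUT&RUN
comparison assumes, with ground truth recorded for every planted effect:

* per-bin coverage is Poisson around a shared underlying profile —
  a flat background rate plus flat-top enrichments over peak footprints
  (flat tops give length-scaled abundance a closed-form expectation);
* each sample is multiplied by a known global scale factor (emulating
  sequencing-depth differences; the default range U[0.9, 1.1] reflects
  samples sequenced to closely matched depths);
* shared intergenic artifact spikes of identical absolute height are
  injected into every antibody track at the same bins (emulating spurious
  alignment pile-ups);
* the first mark carries condition-specific differential footprints with
  known log2 fold changes between the two timepoints;
* an H3K27me1-like mark is restricted to the bodies of a known gene subset;
* per-gene expression counts are negative-binomial, with genes under
  promoters that gain the first mark repressed at the late timepoint;
* the replicate count matrix for differential testing is Gaussian on the
  log2 scale with per-region variances drawn from a scaled
  inverse-chi-square — exactly the hierarchical model under which the
  moderated t-statistic is calibrated.

Everything is bitwise deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as ckio
from .genome import BinnedTrack, GeneModel, Genome, Region, RegionSet
from .normalize import find_local_maxima

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "inject_artifacts",
    "simulate_counts_matrix",
    "thin_track",
]

DEFAULT_MARKS: Dict[str, int] = {
    "H2AK119ub": 300,
    "H3K27me3": 200,
    "H3K4me3": 250,
    "IgG": 0,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; see module docstring for the
    rationale behind the defaults."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    bin_width: int = 50
    background_rate: float = 2.0
    marks: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MARKS))
    timepoints: Tuple[str, str] = ("early", "late")
    n_replicates: int = 2
    peak_height_log_mean: float = math.log(30.0)
    peak_height_log_sd: float = 0.8
    peak_width_bins: Tuple[int, int] = (6, 40)
    scale_factors: Optional[Dict[str, float]] = None  # sample id -> factor
    scale_factor_range: Tuple[float, float] = (0.9, 1.1)
    poisson_noise: bool = True
    n_artifacts: int = 15
    artifact_multiplier: float = 10.0
    n_differential: int = 60
    diff_log2fc_sd: float = 1.5
    n_genes: int = 300
    gene_length_range: Tuple[int, int] = (2_000, 15_000)
    exons_per_gene: Tuple[int, int] = (2, 8)
    me1_enriched_fraction: float = 0.3
    me1_height: float = 10.0
    expression_log_mean: float = math.log(200.0)
    expression_log_sd: float = 1.0
    expression_nb_dispersion: float = 0.3
    include_me1: bool = True
    include_rna: bool = True

    def validate(self, genome: Genome) -> None:
        for mark, n in self.marks.items():
            need = n * (self.peak_width_bins[0] + self.peak_width_bins[1]) // 2
            if need * self.bin_width > self.n_chroms * self.chrom_length:
                raise ValueError(f"{mark}: {n} peaks cannot fit in the genome")

    def save(self, path) -> None:
        """Plain-text key=value dump (tuples/dicts as JSON literals)."""
        with open(path, "w") as fh:
            for key, val in self.__dict__.items():
                fh.write(f"{key} = {json.dumps(val)}\n")

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        kwargs = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                kwargs[key.strip()] = json.loads(val.strip())
        for key in ("timepoints", "peak_width_bins", "scale_factor_range",
                    "gene_length_range", "exons_per_gene"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    scale_factors: Dict[str, float]
    artifact_positions: List[Tuple[str, int]]  # (chrom, bin start position)
    artifact_height: float
    differential: pd.DataFrame  # region_id, chrom, start, end, log2fc
    me1_genes: List[str]
    expression: pd.DataFrame  # gene_id, mu_early, mu_late, log2fc

    def save(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        scalars = {
            "scale_factors": self.scale_factors,
            "artifact_positions": [[c, int(p)] for c, p in self.artifact_positions],
            "artifact_height": self.artifact_height,
            "me1_genes": self.me1_genes,
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(scalars, fh, indent=1, sort_keys=True)
        self.differential.to_csv(
            os.path.join(outdir, "truth_differential.tsv"), sep="\t", index=False
        )
        self.expression.to_csv(
            os.path.join(outdir, "truth_expression.tsv"), sep="\t", index=False
        )

    @classmethod
    def load(cls, outdir) -> "GroundTruth":
        with open(os.path.join(outdir, "truth.json")) as fh:
            scalars = json.load(fh)
        diff = pd.read_csv(
            os.path.join(outdir, "truth_differential.tsv"), sep="\t",
            dtype={"region_id": str, "chrom": str},
        )
        expr = pd.read_csv(
            os.path.join(outdir, "truth_expression.tsv"), sep="\t",
            dtype={"gene_id": str},
        )
        return cls(
            scale_factors=dict(scalars["scale_factors"]),
            artifact_positions=[(c, int(p)) for c, p in scalars["artifact_positions"]],
            artifact_height=float(scalars["artifact_height"]),
            differential=diff,
            me1_genes=list(scalars["me1_genes"]),
            expression=expr,
        )


@dataclass
class SimulatedExperiment:
    genome: Genome
    genes: List[GeneModel]
    tracks: Dict[str, BinnedTrack]  # sample id -> track
    peaks: Dict[Tuple[str, str], RegionSet]  # (mark, timepoint) -> regions
    counts: pd.DataFrame  # per-gene expression counts, one column per (tp, rep)
    truth: GroundTruth
    config: SimulationConfig

    def sample_ids(self, mark: Optional[str] = None, timepoint: Optional[str] = None):
        out = []
        for sid in self.tracks:
            m, tp, _ = sid.rsplit("_", 2)
            if (mark is None or m == mark) and (timepoint is None or tp == timepoint):
                out.append(sid)
        return out

    def write(self, outdir) -> None:
        """Emit the experiment as the same text formats the readers accept."""
        os.makedirs(outdir, exist_ok=True)
        self.config.save(os.path.join(outdir, "config.txt"))
        ckio.save_genes(self.genes, os.path.join(outdir, "genes.tsv"))
        for sid, track in self.tracks.items():
            ckio.save_track(track, os.path.join(outdir, f"{sid}.bedGraph"))
        for (mark, tp), rs in self.peaks.items():
            ckio.save_regions(rs, os.path.join(outdir, f"peaks_{mark}_{tp}.bed"))
        self.counts.to_csv(os.path.join(outdir, "expression_counts.tsv"), sep="\t")
        self.truth.save(outdir)


def _place_intervals(
    rng: np.random.Generator,
    genome: Genome,
    n: int,
    width_sampler,
    margin_bins: int = 2,
) -> List[Region]:
    """Place ``n`` non-overlapping bin-aligned intervals across chromosomes."""
    w = genome.bin_width
    chroms = list(genome.chroms)
    counts = np.full(len(chroms), n // len(chroms))
    counts[: n % len(chroms)] += 1
    regions: List[Region] = []
    for chrom, k in zip(chroms, counts):
        if k == 0:
            continue
        nbins = genome.n_bins(chrom)
        widths = np.asarray([width_sampler() for _ in range(k)], dtype=np.int64)
        free = nbins - 2 * margin_bins - int(widths.sum()) - (k - 1) * margin_bins
        if free < 0:
            raise ValueError(f"{chrom}: cannot fit {k} intervals")
        gaps = rng.multinomial(free, np.ones(k + 1) / (k + 1))
        cursor = margin_bins
        for i in range(k):
            cursor += int(gaps[i])
            start_bin = cursor
            end_bin = start_bin + int(widths[i])
            regions.append(Region(chrom, start_bin * w, min(end_bin * w, genome.length(chrom))))
            cursor = end_bin + margin_bins
    return regions


def _make_genes(rng: np.random.Generator, genome: Genome, cfg: SimulationConfig) -> List[GeneModel]:
    lo, hi = cfg.gene_length_range
    w = genome.bin_width

    def width():
        return max(2, int(rng.integers(lo, hi + 1)) // w)

    bodies = _place_intervals(rng, genome, cfg.n_genes, width, margin_bins=4)
    genes: List[GeneModel] = []
    for i, body in enumerate(bodies):
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        cuts = np.sort(rng.choice(np.arange(body.start + 1, body.end), size=2 * k, replace=False))
        exons = tuple((int(cuts[2 * j]), int(cuts[2 * j + 1])) for j in range(k))
        genes.append(GeneModel(f"gene{i:04d}", body.chrom, strand, body.start, body.end, exons))
    return genes


def inject_artifacts(
    track: BinnedTrack,
    positions: Sequence[Tuple[str, int]],
    multiplier: float,
    genes: Optional[Sequence[GeneModel]] = None,
    height: Optional[float] = None,
) -> BinnedTrack:
    """Add narrow artifact spikes at the given (chrom, position) bins.

    The spike height is ``multiplier`` x the track's 99th percentile of
    local-maxima heights unless an explicit ``height`` is supplied (the
    generator supplies one so that spikes are identical across all samples
    and marks they are injected into).  Positions inside a gene body (by
    bin-midpoint) are rejected.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    out = track.copy()
    if multiplier == 0 or not positions:
        return out
    if height is None:
        maxima = find_local_maxima(track)
        if len(maxima) == 0:
            raise ValueError("track has no local maxima to anchor artifact height")
        height = multiplier * float(np.percentile(maxima.heights, 99))
    else:
        height = float(height)
    w = track.genome.bin_width
    if genes:
        for chrom, pos in positions:
            b = pos // w
            lo, hi = track.genome.bin_span(chrom, b)
            mid = (lo + hi) // 2
            for g in genes:
                if g.chrom == chrom and g.contains(mid):
                    raise ValueError(
                        f"artifact position {chrom}:{pos} lies inside gene body {g.gene_id}"
                    )
    for chrom, pos in positions:
        out.values[chrom][pos // w] += height
    return out


def simulate_experiment(cfg: SimulationConfig) -> SimulatedExperiment:
    """Generate the full synthetic experiment described in the module docstring."""
    genome = Genome(
        {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chroms)},
        bin_width=cfg.bin_width,
    )
    cfg.validate(genome)
    rng = np.random.default_rng(cfg.seed)
    w = cfg.bin_width

    genes = _make_genes(rng, genome, cfg)

    # --- peak footprints and heights per mark --------------------------------
    marks = dict(cfg.marks)
    peak_regions: Dict[str, List[Region]] = {}
    peak_heights: Dict[str, np.ndarray] = {}
    w_lo, w_hi = cfg.peak_width_bins
    for mark, n_peaks in marks.items():
        if n_peaks == 0:
            peak_regions[mark] = []
            peak_heights[mark] = np.zeros(0)
            continue
        regions = _place_intervals(
            rng, genome, n_peaks, lambda: int(rng.integers(w_lo, w_hi + 1))
        )
        heights = rng.lognormal(cfg.peak_height_log_mean, cfg.peak_height_log_sd, len(regions))
        peak_regions[mark] = regions
        peak_heights[mark] = heights

    # --- differential program on the first mark ------------------------------
    primary = next(iter(marks))
    n_primary = len(peak_regions[primary])
    n_diff = min(cfg.n_differential, n_primary)
    diff_idx = np.sort(rng.choice(n_primary, size=n_diff, replace=False)) if n_diff else np.array([], int)
    lfc = np.zeros(n_primary)
    if n_diff:
        lfc[diff_idx] = rng.normal(0.0, cfg.diff_log2fc_sd, n_diff)
    diff_rows = []
    for i in diff_idx:
        r = peak_regions[primary][i]
        diff_rows.append((r.id, r.chrom, r.start, r.end, float(lfc[i])))
    differential = pd.DataFrame(
        diff_rows, columns=["region_id", "chrom", "start", "end", "log2fc"]
    )

    # --- gene-body-restricted me1-like mark -----------------------------------
    me1_genes: List[str] = []
    if cfg.include_me1 and genes:
        n_me1 = int(round(cfg.me1_enriched_fraction * len(genes)))
        idx = np.sort(rng.choice(len(genes), size=n_me1, replace=False))
        me1_genes = [genes[i].gene_id for i in idx]
        marks["H3K27me1"] = n_me1
        peak_regions["H3K27me1"] = [genes[i].body for i in idx]
        peak_heights["H3K27me1"] = np.full(n_me1, cfg.me1_height)

    # --- expression program ----------------------------------------------------
    mu_early = rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sd, len(genes))
    expr_lfc = np.zeros(len(genes))
    if n_diff and genes:
        up_regions = RegionSet(
            [peak_regions[primary][i] for i in diff_idx if lfc[i] > 0], genome
        )
        promoters = RegionSet([g.promoter(1000, genome) for g in genes], genome)
        hit = promoters.overlaps_any(up_regions) if len(up_regions) else np.zeros(len(genes), bool)
        expr_lfc[hit] = -1.0  # promoter gain of the repressive mark halves expression
    mu_late = mu_early * np.exp2(expr_lfc)
    expression = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "mu_early": mu_early,
            "mu_late": mu_late,
            "log2fc": expr_lfc,
        }
    )

    # --- per-(mark, timepoint) mean profiles ----------------------------------
    def blank() -> Dict[str, np.ndarray]:
        return {c: np.full(genome.n_bins(c), float(cfg.background_rate)) for c in genome.chroms}

    profiles: Dict[Tuple[str, str], Dict[str, np.ndarray]] = {}
    peaks_out: Dict[Tuple[str, str], RegionSet] = {}
    for mark in marks:
        for tp_i, tp in enumerate(cfg.timepoints):
            prof = blank()
            heights = peak_heights[mark].copy()
            if mark == primary and tp_i == 1 and n_diff:
                heights[diff_idx] *= np.exp2(lfc[diff_idx])
            for region, h in zip(peak_regions[mark], heights):
                b0, b1 = region.start // w, -(-region.end // w)
                prof[region.chrom][b0:b1] += h
            profiles[(mark, tp)] = prof
            peaks_out[(mark, tp)] = RegionSet(list(peak_regions[mark]), genome, merged=True)

    if cfg.include_rna:
        for tp, col in zip(cfg.timepoints, ("mu_early", "mu_late")):
            prof = blank()
            for g, mu in zip(genes, expression[col]):
                b0, b1 = g.start // w, -(-g.end // w)
                prof[g.chrom][b0:b1] += mu / 20.0  # coverage height ~ expression level
            profiles[("RNA", tp)] = prof

    # --- sample tracks ----------------------------------------------------------
    sample_order: List[str] = []
    for mark in list(marks) + (["RNA"] if cfg.include_rna else []):
        for tp in cfg.timepoints:
            for rep in range(1, cfg.n_replicates + 1):
                sample_order.append(f"{mark}_{tp}_rep{rep}")

    if cfg.scale_factors is not None:
        factors = {sid: float(cfg.scale_factors.get(sid, 1.0)) for sid in sample_order}
    else:
        lo, hi = cfg.scale_factor_range
        factors = {sid: float(rng.uniform(lo, hi)) for sid in sample_order}

    tracks: Dict[str, BinnedTrack] = {}
    for sid in sample_order:
        mark, tp, _ = sid.rsplit("_", 2)
        prof = profiles[(mark, tp)]
        vals = {}
        for chrom, lam in prof.items():
            base = rng.poisson(lam).astype(float) if cfg.poisson_noise else lam.copy()
            vals[chrom] = base * factors[sid]
        tracks[sid] = BinnedTrack(genome, vals, validate=False)

    # --- shared intergenic artifacts ---------------------------------------------
    artifact_positions: List[Tuple[str, int]] = []
    artifact_height = 0.0
    if cfg.n_artifacts > 0 and cfg.artifact_multiplier > 0:
        genic = RegionSet([g.body for g in genes], genome).bin_mask() if genes else {
            c: np.zeros(genome.n_bins(c), bool) for c in genome.chroms
        }
        candidates = []
        for chrom in genome.chroms:
            mask = genic.get(chrom, np.zeros(genome.n_bins(chrom), bool))
            free = np.flatnonzero(~mask)
            free = free[(free > 2) & (free < genome.n_bins(chrom) - 3)]
            candidates.extend((chrom, int(b)) for b in free[::4])  # >= 3-bin separation
        picks = rng.choice(len(candidates), size=min(cfg.n_artifacts, len(candidates)), replace=False)
        artifact_positions = sorted(
            (candidates[i][0], candidates[i][1] * w) for i in np.sort(picks)
        )
        first = tracks[sample_order[0]]
        maxima = find_local_maxima(first)
        artifact_height = cfg.artifact_multiplier * float(np.percentile(maxima.heights, 99))
        for sid in sample_order:
            mark = sid.rsplit("_", 2)[0]
            if mark == "RNA":
                continue  # alignment artifacts modelled for the antibody tracks only
            tracks[sid] = inject_artifacts(
                tracks[sid], artifact_positions, cfg.artifact_multiplier,
                genes=None, height=artifact_height,
            )

    # --- expression counts ---------------------------------------------------------
    disp = cfg.expression_nb_dispersion
    count_cols = {}
    for tp, col in zip(cfg.timepoints, ("mu_early", "mu_late")):
        mu = expression[col].to_numpy()
        for rep in range(1, cfg.n_replicates + 1):
            # NB via gamma-Poisson mixture; dispersion = 1/size
            shape = 1.0 / disp
            lam = rng.gamma(shape, mu * disp)
            count_cols[f"{tp}_rep{rep}"] = rng.poisson(lam)
    counts = pd.DataFrame(count_cols, index=[g.gene_id for g in genes])
    counts.index.name = "gene_id"

    truth = GroundTruth(
        scale_factors=factors,
        artifact_positions=artifact_positions,
        artifact_height=artifact_height,
        differential=differential,
        me1_genes=me1_genes,
        expression=expression,
    )
    return SimulatedExperiment(genome, genes, tracks, peaks_out, counts, truth, cfg)


def thin_track(track: BinnedTrack, keep_fraction: float, rng: np.random.Generator) -> BinnedTrack:
    """Binomially subsample integer bin counts to ``keep_fraction`` depth."""
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    vals = {}
    for chrom, v in track.values.items():
        rounded = np.rint(v)
        if not np.allclose(v, rounded):
            raise ValueError("thinning requires integer bin counts (an unscaled track)")
        vals[chrom] = rng.binomial(rounded.astype(np.int64), keep_fraction).astype(float)
    return BinnedTrack(track.genome, vals, validate=False)


def simulate_counts_matrix(
    n_regions: int = 2000,
    n_per_condition: int = 4,
    frac_differential: float = 0.0,
    log2fc: float = 2.0,
    d0: float = 4.0,
    s0: float = 0.4,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    conditions: Tuple[str, str] = ("early", "late"),
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Log2-scale replicate count matrix under the moderated-t hierarchy.

    Per-region variances are drawn as ``d0*s0^2 / chi2(d0)`` (a scaled
    inverse-chi-square with prior df ``d0`` and prior sd ``s0``); replicate
    noise is Gaussian on the log2 scale.  A ``frac_differential`` fraction
    of regions is shifted by ``+-log2fc`` (random sign) in the second
    condition.

    Returns ``(matrix, truth)``: the regions x samples DataFrame and a
    truth table with columns ``log2fc`` and ``is_differential``.
    """
    if n_per_condition < 2:
        raise ValueError("need >= 2 replicates per condition")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_diff = int(round(frac_differential * n_regions))
    ids = [f"region{i:05d}" for i in range(n_regions)]

    mu = rng.normal(baseline_mean, baseline_sd, n_regions)
    s2 = d0 * s0**2 / rng.chisquare(d0, n_regions) if np.isfinite(d0) else np.full(n_regions, s0**2)
    true_lfc = np.zeros(n_regions)
    if n_diff:
        idx = rng.choice(n_regions, size=n_diff, replace=False)
        true_lfc[idx] = log2fc * rng.choice([-1.0, 1.0], size=n_diff)

    cols = {}
    sd = np.sqrt(s2)
    for rep in range(1, n_per_condition + 1):
        cols[f"{conditions[0]}_rep{rep}"] = mu + rng.normal(0.0, sd)
    for rep in range(1, n_per_condition + 1):
        cols[f"{conditions[1]}_rep{rep}"] = mu + true_lfc + rng.normal(0.0, sd)
    matrix = pd.DataFrame(cols, index=pd.Index(ids, name="region_id"))
    truth = pd.DataFrame(
        {"log2fc": true_lfc, "is_differential": true_lfc != 0.0},
        index=matrix.index,
    )
    return matrix, truth
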