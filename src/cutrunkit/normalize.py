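"""Percentile-based normalization of binned coverage tracks.

Two coverage tracks of the same mark sequenced to different effective depths
differ, to first order, by a global multiplicative factor.  Rather than
normalizing to total read count (which is dominated by background), the
procedure implemented here equalizes the *enriched* portion of the signal:

1. find local maxima of each binned track and record their heights;
2. exclude maxima falling in a blacklist of recurrent intergenic artifacts
   (spurious alignment pile-ups shared across unrelated antibodies, whose
   heights do not scale with genuine signal and distort the upper tail);
3. compute the 99th percentile of the remaining maxima heights in each
   sample; the ratio of these percentiles is the scaling factor, and every
   bin of the target sample is multiplied by it.

A local maximum is a bin strictly higher than its left neighbour and at
least as high as its right neighbour, which collapses plateau runs to their
leftmost bin; chromosome-boundary bins are never maxima.  Percentiles are
computed by linear interpolation on the sorted heights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GeneModel, Genome, Region, RegionSet, _check_same_genome

__all__ = [
    "LocalMaxima",
    "ScalingFactor",
    "find_local_maxima",
    "build_blacklist",
    "compute_scaling_factor",
    "apply_scaling",
    "spikein_specificity",
]


@dataclass
class LocalMaxima:
    """Local maxima of a binned track: one row per maximum.

    ``table`` has columns ``chrom``, ``bin`` (bin index), ``pos`` (genomic
    position of the bin start) and ``height``; positions are strictly
    increasing within each chromosome.
    """

    table: pd.DataFrame
    genome: Genome

    @property
    def heights(self) -> np.ndarray:
        return self.table["height"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def exclude(self, blacklist: Optional[RegionSet]) -> "LocalMaxima":
        """Drop maxima whose bin overlaps any blacklist region."""
        if blacklist is None or len(blacklist) == 0 or len(self.table) == 0:
            return self
        mask = blacklist.bin_mask()
        keep = np.ones(len(self.table), dtype=bool)
        for i, (chrom, b) in enumerate(zip(self.table["chrom"], self.table["bin"])):
            keep[i] = not mask[chrom][b]
        return LocalMaxima(self.table[keep].reset_index(drop=True), self.genome)


@dataclass(frozen=True)
class ScalingFactor:
    """Multiplicative factor normalizing a target track to a reference."""

    value: float
    percentile: float = 99.0
    n_reference: int = 0
    n_target: int = 0
    reference_id: Optional[str] = None
    target_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"scaling factor must be positive, got {self.value}")
        if not (0 < self.percentile < 100):
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")


def find_local_maxima(track: BinnedTrack, min_height: float = 0.0) -> LocalMaxima:
    """Locate local maxima of a binned track.

    Bin ``i`` is a maximum iff ``v[i] > v[i-1]`` and ``v[i] >= v[i+1]``
    (plateaus collapse to their leftmost bin).  Boundary bins are excluded,
    and maxima with height <= ``min_height`` are dropped.
    """
    frames: List[pd.DataFrame] = []
    w = track.genome.bin_width
    for chrom in track.genome.chroms:
        v = track.values[chrom]
        if v.size < 3:
            continue
        mid = v[1:-1]
        is_max = (mid > v[:-2]) & (mid >= v[2:]) & (mid > min_height)
        bins = np.flatnonzero(is_max) + 1
        if bins.size:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "bin": bins,
                        "pos": bins * w,
                        "height": v[bins],
                    }
                )
            )
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["chrom", "bin", "pos", "height"])
    return LocalMaxima(table, track.genome)


def build_blacklist(
    maxima_by_sample: Mapping[str, LocalMaxima],
    genes: Sequence[GeneModel],
    recurrence: float = 1.0,
    height_quantile: float = 0.999,
) -> RegionSet:
    """Identify recurrent extreme intergenic maxima across samples.

    A bin is blacklisted when, in at least ``recurrence`` fraction of the
    samples, it carries (within +-1 bin) an intergenic local maximum whose
    height exceeds that sample's ``height_quantile`` of maxima heights.
    Genuine peaks do not recur at bin resolution across unrelated
    antibodies, so with samples spanning several marks (ideally including an
    IgG control) the survivors are shared alignment artifacts.

    Returns merged single-bin regions.
    """
    if len(maxima_by_sample) < 2:
        raise ValueError("blacklist construction requires >= 2 independent samples")
    if not (0 < recurrence <= 1):
        raise ValueError(f"recurrence must be in (0, 1], got {recurrence}")
    samples = list(maxima_by_sample.values())
    genome = samples[0].genome

    # merged gene bodies for the intergenic filter (bin midpoint rule)
    bodies = RegionSet([g.body for g in genes], genome).merge().by_chrom() if genes else {}

    def _is_intergenic(chrom: str, b: int) -> bool:
        lo, hi = genome.bin_span(chrom, b)
        mid = (lo + hi) // 2
        if chrom not in bodies:
            return True
        starts, ends = bodies[chrom]
        j = int(np.searchsorted(starts, mid, side="right"))
        return not (j > 0 and ends[j - 1] > mid)

    candidate_bins: List[Dict[str, np.ndarray]] = []
    for lm in samples:
        if lm.genome != genome:
            raise ValueError("all samples must share one genome")
        if len(lm.table) == 0:
            candidate_bins.append({})
            continue
        thr = float(np.quantile(lm.heights, height_quantile))
        cand = lm.table[lm.table["height"] > thr]
        per_chrom: Dict[str, np.ndarray] = {}
        for chrom, sub in cand.groupby("chrom", sort=True):
            bins = np.asarray(
                [b for b in sub["bin"].to_numpy() if _is_intergenic(chrom, int(b))],
                dtype=np.int64,
            )
            if bins.size:
                per_chrom[str(chrom)] = np.sort(bins)
        candidate_bins.append(per_chrom)

    n_needed = recurrence * len(samples)
    union: Dict[str, set] = {}
    for per_chrom in candidate_bins:
        for chrom, bins in per_chrom.items():
            union.setdefault(chrom, set()).update(int(b) for b in bins)

    regions: List[Region] = []
    for chrom in sorted(union):
        for b in sorted(union[chrom]):
            count = 0
            for per_chrom in candidate_bins:
                bins = per_chrom.get(chrom)
                if bins is not None and bins.size:
                    j = int(np.searchsorted(bins, b - 1))
                    if j < bins.size and bins[j] <= b + 1:
                        count += 1
            if count >= n_needed - 1e-9:
                lo, hi = genome.bin_span(chrom, b)
                regions.append(Region(chrom, lo, hi))
    return RegionSet(regions, genome).merge()


def compute_scaling_factor(
    reference: BinnedTrack,
    target: BinnedTrack,
    blacklist: Optional[RegionSet] = None,
    percentile: float = 99.0,
    min_height: float = 0.0,
    min_maxima: int = 100,
    reference_id: Optional[str] = None,
    target_id: Optional[str] = None,
) -> ScalingFactor:
    """Ratio of blacklist-excluded local-maxima height percentiles.

    ``factor = P(reference maxima heights) / P(target maxima heights)``;
    multiplying the target track by the factor equalizes the two samples'
    enriched-signal scale.
    """
    _check_same_genome(reference, target)
    ref_max = find_local_maxima(reference, min_height=min_height).exclude(blacklist)
    tgt_max = find_local_maxima(target, min_height=min_height).exclude(blacklist)
    if len(ref_max) < min_maxima or len(tgt_max) < min_maxima:
        raise ValueError(
            f"too few non-blacklisted maxima (reference {len(ref_max)}, "
            f"target {len(tgt_max)}; need >= {min_maxima})"
        )
    p_ref = float(np.percentile(ref_max.heights, percentile))
    p_tgt = float(np.percentile(tgt_max.heights, percentile))
    if p_tgt <= 0:
        raise ValueError("target percentile height is zero; cannot scale")
    return ScalingFactor(
        value=p_ref / p_tgt,
        percentile=percentile,
        n_reference=len(ref_max),
        n_target=len(tgt_max),
        reference_id=reference_id,
        target_id=target_id,
    )


def apply_scaling(track: BinnedTrack, factor: Union[ScalingFactor, float]) -> BinnedTrack:
    """Multiply every bin by the scaling factor."""
    value = factor.value if isinstance(factor, ScalingFactor) else float(factor)
    if value == 1.0:
        return track.copy()
    return track.scale(value)


def spikein_specificity(counts: pd.DataFrame) -> pd.DataFrame:
    """Antibody specificity against a spiked-in modified-nucleosome panel.

    ``counts`` is antibodies x modifications of non-negative read counts;
    the result normalizes each antibody row to the total reads derived from
    all spiked-in modifications, so rows sum to 1.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("spike-in counts must be non-negative")
    row_sums = arr.sum(axis=1)
    zero = np.flatnonzero(row_sums == 0)
    if zero.size:
        raise ValueError(
            f"antibody row(s) with zero total spike-in reads: "
            f"{list(counts.index[zero])}"
        )
    return counts.div(row_sums, axis=0)
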