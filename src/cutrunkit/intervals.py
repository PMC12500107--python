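"""Interval algebra and locus classification.

The semantics follow the conventions used throughout comparative CUT&RUN
analyses of chromatin marks:

* *overlap* means >= 1 bp of shared sequence (the bedtools intersect
  default);
* *intersection* reports the maximal intervals covered by at least one
  region of each input set;
* *subtraction* is region-level, not base-level: a region of ``a`` survives
  only if it overlaps **no** region of ``b``.  This matches how "peak
  regions that did not overlap" classes (e.g. PRC1-only loci, H3K4me3-only
  promoters) are defined — whole peaks are kept or discarded, never clipped.
"""

from __future__ import annotations

from functools import reduce
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome import GeneModel, Genome, GenomeMismatchError, Region, RegionSet, _check_same_genome

__all__ = [
    "intersect_regions",
    "subtract_regions",
    "consensus_regions",
    "overlap_fraction",
    "classify_promoters",
    "classify_h2aub_loci",
    "closest_feature",
    "annotate_location",
]


def _intersect_chrom(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> List[Tuple[int, int]]:
    """Two-pointer sweep over two sorted, disjoint interval lists."""
    out: List[Tuple[int, int]] = []
    i = j = 0
    while i < len(a_starts) and j < len(b_starts):
        lo = max(a_starts[i], b_starts[j])
        hi = min(a_ends[i], b_ends[j])
        if lo < hi:
            out.append((int(lo), int(hi)))
        if a_ends[i] <= b_ends[j]:
            i += 1
        else:
            j += 1
    return out


def intersect_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Maximal intervals covered by >= 1 region of ``a`` AND >= 1 of ``b``."""
    _check_same_genome(a, b)
    am, bm = a.merge().by_chrom(), b.merge().by_chrom()
    regions: List[Region] = []
    for chrom in am:
        if chrom not in bm:
            continue
        for lo, hi in _intersect_chrom(*am[chrom], *bm[chrom]):
            regions.append(Region(chrom, lo, hi))
    return RegionSet(regions, a.genome, merged=True)


def subtract_regions(a: RegionSet, b: RegionSet) -> RegionSet:
    """Regions of ``a`` with zero overlap against all of ``b``, kept whole."""
    _check_same_genome(a, b)
    keep = ~a.overlaps_any(b)
    return RegionSet([r for r, k in zip(a, keep) if k], a.genome, merged=a.merged)


def consensus_regions(replicates: Sequence[RegionSet]) -> RegionSet:
    """Intervals present (>= 1 bp) in every replicate peak set.

    Reported as the iterated-intersection intervals, the usual way
    replicate-shared peak regions are defined.
    """
    if len(replicates) < 2:
        raise ValueError(f"consensus requires >= 2 replicate sets, got {len(replicates)}")
    return reduce(intersect_regions, replicates)


def overlap_fraction(a: RegionSet, b: RegionSet) -> Tuple[float, float]:
    """(fraction of ``a`` regions overlapping ``b``, and vice versa)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("overlap fraction is undefined for an empty region set")
    return (
        float(a.overlaps_any(b).mean()),
        float(b.overlaps_any(a).mean()),
    )


def classify_promoters(k4me3: RegionSet, k27me3: RegionSet) -> Tuple[RegionSet, RegionSet]:
    """Split H3K4me3 peak regions into bivalent and H3K4me3-only classes.

    Bivalent regions are the intersections of H3K4me3 and H3K27me3 peaks;
    H3K4me3-only regions are the H3K4me3 peaks that overlap no H3K27me3
    peak at all.  The two outputs never overlap each other.
    """
    bivalent = intersect_regions(k4me3, k27me3)
    k4_only = subtract_regions(k4me3, k27me3)
    return bivalent, k4_only


def classify_h2aub_loci(h2aub: RegionSet, k27me3: RegionSet) -> Tuple[RegionSet, RegionSet]:
    """Split H2AK119ub peaks into PRC1-PRC2 co-occupied and PRC1-only loci.

    Co-occupied loci are intersections with H3K27me3 peaks; PRC1-only loci
    are whole H2AK119ub peaks with no H3K27me3 overlap, so the PRC1-only
    count plus the count of overlapping H2AK119ub peaks equals the input
    peak count.
    """
    co_occupied = intersect_regions(h2aub, k27me3)
    prc1_only = subtract_regions(h2aub, k27me3)
    return co_occupied, prc1_only


def _region_gene_distance(r: Region, g: GeneModel) -> int:
    """0 when overlapping; otherwise the bp gap between region and body."""
    if r.chrom != g.chrom:
        raise ValueError("distance undefined across chromosomes")
    return max(g.start - r.end, r.start - g.end, 0)


def closest_feature(
    regions: RegionSet,
    genes: Sequence[GeneModel],
    max_dist: int = 10_000,
) -> List[Tuple[Optional[GeneModel], Optional[int]]]:
    """Nearest gene body per region within ``max_dist`` bp.

    Returns one ``(gene, distance)`` pair per region (in region order), or
    ``(None, None)`` when no gene body lies within ``max_dist``.  Distance is
    0 for overlaps; ties are broken by smaller gene start, then gene id.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: (g.start, g.gene_id))

    out: List[Tuple[Optional[GeneModel], Optional[int]]] = []
    for r in regions:
        best: Optional[GeneModel] = None
        best_d = max_dist + 1
        for g in by_chrom.get(r.chrom, ()):
            d = _region_gene_distance(r, g)
            if d < best_d:  # earlier genes win ties via sort order
                best, best_d = g, d
        out.append((best, best_d) if best is not None else (None, None))
    return out


def annotate_location(
    summits: RegionSet, genes: Sequence[GeneModel]
) -> Tuple[List[str], Dict[str, float]]:
    """Label each summit intragenic/intergenic by its midpoint.

    A summit is intragenic iff its midpoint falls within any gene body.
    Returns the per-summit labels plus the fraction of each label.
    """
    bodies = RegionSet([g.body for g in genes], summits.genome) if genes else None
    merged = bodies.merge().by_chrom() if bodies is not None else {}
    labels: List[str] = []
    for r in summits:
        m = r.midpoint
        label = "intergenic"
        if r.chrom in merged:
            starts, ends = merged[r.chrom]
            j = int(np.searchsorted(starts, m, side="right"))
            if j > 0 and ends[j - 1] > m:
                label = "intragenic"
        labels.append(label)
    n = max(len(labels), 1)
    fractions = {
        "intragenic": labels.count("intragenic") / n,
        "intergenic": labels.count("intergenic") / n,
    }
    return labels, fractions
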