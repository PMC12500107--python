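"""Core genomic containers: genomes, regions, binned tracks, gene models.

All coordinates are 0-based, half-open ``[start, end)`` (the BED convention).
Coverage tracks are stored as one fixed-width bin-value vector per chromosome
(50 bp bins by default, matching the resolution CUT&RUN coverage is usually
binned at); the last bin of a chromosome may span fewer than ``bin_width``
base pairs when the chromosome length is not a multiple of the bin width.

Every region set and track carries a reference to the :class:`Genome` it was
built against, and operations that combine objects refuse to mix genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Genome",
    "GenomeMismatchError",
    "Region",
    "RegionSet",
    "BinnedTrack",
    "GeneModel",
]


class GenomeMismatchError(ValueError):
    """Raised when two objects that must share a Genome do not."""


@dataclass(eq=True)
class Genome:
    """Chromosome names/lengths plus the track bin width.

    Parameters
    ----------
    lengths
        Ordered mapping of chromosome name to length in base pairs.
    bin_width
        Width of track bins in base pairs (default 50).
    """

    lengths: Dict[str, int]
    bin_width: int = 50

    def __post_init__(self) -> None:
        self.lengths = dict(self.lengths)
        if not self.lengths:
            raise ValueError("genome must contain at least one chromosome")
        for chrom, length in self.lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            self.lengths[chrom] = int(length)
        if int(self.bin_width) <= 0:
            raise ValueError(f"bin_width must be positive, got {self.bin_width}")
        self.bin_width = int(self.bin_width)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str) -> int:
        return -(-self.length(chrom) // self.bin_width)

    def bin_span(self, chrom: str, bin_index: int) -> Tuple[int, int]:
        """Genomic extent [start, end) of one bin (last bin may be short)."""
        w = self.bin_width
        return bin_index * w, min((bin_index + 1) * w, self.length(chrom))

    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)


def _check_same_genome(a, b) -> None:
    if a.genome != b.genome:
        raise GenomeMismatchError("objects reference different genomes")


@dataclass(frozen=True)
class Region:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def id(self) -> str:
        """Stable identifier: the name if set, else ``chrom:start-end``."""
        return self.name if self.name is not None else f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class RegionSet:
    """An ordered collection of regions, sorted by (chrom, start, end).

    The ``merged`` flag records whether the set is known to contain no
    overlapping regions (output of :meth:`merge` and of interval-algebra
    intersection).
    """

    def __init__(self, regions: Sequence[Region], genome: Genome, merged: bool = False):
        self.genome = genome
        regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
        for r in regs:
            if r.chrom not in genome:
                raise KeyError(f"region on unknown chromosome {r.chrom!r}")
            if r.end > genome.length(r.chrom):
                raise ValueError(
                    f"region {r.chrom}:{r.start}-{r.end} exceeds chromosome "
                    f"length {genome.length(r.chrom)}"
                )
        self.regions: Tuple[Region, ...] = tuple(regs)
        self.merged = bool(merged)
        self._arrays: Optional[Dict[str, Tuple[np.ndarray, np.ndarray]]] = None

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.genome == other.genome and self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} regions, merged={self.merged})"

    # -- derived views -----------------------------------------------------
    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) integer arrays, cached."""
        if self._arrays is None:
            arrays: Dict[str, List[List[int]]] = {}
            for r in self.regions:
                arrays.setdefault(r.chrom, [[], []])
                arrays[r.chrom][0].append(r.start)
                arrays[r.chrom][1].append(r.end)
            self._arrays = {
                c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
                for c, (s, e) in arrays.items()
            }
        return self._arrays

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.regions]

    def total_bp(self) -> int:
        return sum(r.length for r in self.merge())

    def merge(self) -> "RegionSet":
        """Collapse overlapping (or touching) regions into maximal intervals."""
        if self.merged:
            return self
        out: List[Region] = []
        for r in self.regions:
            if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
                if r.end > out[-1].end:
                    out[-1] = Region(r.chrom, out[-1].start, r.end)
            else:
                out.append(Region(r.chrom, r.start, r.end))
        return RegionSet(out, self.genome, merged=True)

    def overlaps_any(self, other: "RegionSet") -> np.ndarray:
        """Boolean per region of self: does it overlap >= 1 bp of ``other``?"""
        _check_same_genome(self, other)
        merged = other.merge().by_chrom()
        flags = np.zeros(len(self), dtype=bool)
        for i, r in enumerate(self.regions):
            if r.chrom not in merged:
                continue
            o_starts, o_ends = merged[r.chrom]
            j = int(np.searchsorted(o_starts, r.end, side="left"))
            # merged intervals have increasing ends, so only interval j-1 can reach r
            flags[i] = j > 0 and o_ends[j - 1] > r.start
        return flags

    def bin_mask(self) -> Dict[str, np.ndarray]:
        """Per-chromosome boolean array marking bins overlapped by any region."""
        w = self.genome.bin_width
        mask = {c: np.zeros(self.genome.n_bins(c), dtype=bool) for c in self.genome.chroms}
        for r in self.regions:
            b0 = r.start // w
            b1 = (r.end - 1) // w
            mask[r.chrom][b0 : b1 + 1] = True
        return mask


class BinnedTrack:
    """Genome-wide coverage in fixed-width bins.

    ``values`` maps each chromosome to a float vector of length
    ``ceil(chrom_length / bin_width)``; values must be finite and >= 0.
    """

    def __init__(self, genome: Genome, values: Mapping[str, np.ndarray], validate: bool = True):
        self.genome = genome
        vals: Dict[str, np.ndarray] = {}
        for chrom in genome.chroms:
            v = np.asarray(values.get(chrom, np.zeros(genome.n_bins(chrom))), dtype=float)
            if v.shape != (genome.n_bins(chrom),):
                raise ValueError(
                    f"{chrom}: expected {genome.n_bins(chrom)} bins, got {v.shape}"
                )
            if validate:
                if not np.all(np.isfinite(v)):
                    raise ValueError(f"{chrom}: track contains non-finite values")
                if np.any(v < 0):
                    raise ValueError(f"{chrom}: track contains negative values")
            vals[chrom] = v
        self.values = vals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinnedTrack):
            return NotImplemented
        return self.genome == other.genome and all(
            np.array_equal(self.values[c], other.values[c]) for c in self.genome.chroms
        )

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.genome, {c: v.copy() for c, v in self.values.items()}, validate=False
        )

    def scale(self, factor: float) -> "BinnedTrack":
        """Return a new track with every bin multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        return BinnedTrack(
            self.genome, {c: v * factor for c, v in self.values.items()}, validate=False
        )

    def flat(self) -> np.ndarray:
        """All bins concatenated in genome chromosome order."""
        return np.concatenate([self.values[c] for c in self.genome.chroms])


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand, TSS, and exon structure.

    The TSS is ``start`` on the + strand and ``end`` on the - strand (the
    half-open end coordinate).  Exons must lie within the body.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid body {self.start}-{self.end}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon {s}-{e} outside body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def body(self) -> Region:
        return Region(self.chrom, self.start, self.end, name=self.gene_id)

    @property
    def exon_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def promoter(self, length: int = 1000, genome: Optional[Genome] = None) -> Region:
        """The ``length`` bp immediately upstream of the TSS, strand-adjusted.

        Clipped to chromosome bounds when a genome is supplied.
        """
        if self.strand == "+":
            lo, hi = self.tss - length, self.tss
        else:
            lo, hi = self.tss, self.tss + length
        lo = max(lo, 0)
        if genome is not None:
            hi = min(hi, genome.length(self.chrom))
        if lo >= hi:  # promoter falls entirely off the chromosome edge
            lo, hi = max(hi - 1, 0), max(hi, 1)
        return Region(self.chrom, lo, hi, name=f"{self.gene_id}:promoter")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end
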