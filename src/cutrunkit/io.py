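"""Readers and writers for the plain-text formats the pipeline touches.

Regions travel as BED3/BED6, coverage tracks as bedGraph (with optional
bigwig *reading* when pyBigWig is installed), gene models as either BED12 or
a six-column table (gene_id, chrom, strand, tss, body, comma-separated
exons), and count tables as TSV.

bedGraph is the on-disk track dialect because it round-trips bit-exactly
through text; :func:`save_track` merges runs of equal-valued bins and omits
zero runs, and :func:`load_track` resamples arbitrary intervals onto the
genome's bins by coverage-weighted mean (uncovered bases count as zero).
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genome import BinnedTrack, GeneModel, Genome, Region, RegionSet

__all__ = [
    "load_regions",
    "save_regions",
    "load_track",
    "save_track",
    "load_genes",
    "save_genes",
    "load_counts",
    "save_counts",
]

_SKIP_PREFIXES = ("#", "track", "browser")


class BedParseError(ValueError):
    """A malformed line in a BED/bedGraph file, reported with its number."""


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

def load_regions(path: Union[str, os.PathLike], genome: Genome) -> RegionSet:
    """Read a BED3+ file into a sorted :class:`RegionSet`.

    Regions exceeding chromosome bounds or naming unknown chromosomes are
    rejected with an error identifying the offending line.
    """
    regions: List[Region] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise BedParseError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom = fields[0]
        if chrom not in genome:
            raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
        try:
            region = Region(chrom, start, end, name=name, score=score)
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: {exc}") from exc
        if end > genome.length(chrom):
            raise BedParseError(
                f"{path}:{lineno}: region end {end} exceeds {chrom} length "
                f"{genome.length(chrom)}"
            )
        regions.append(region)
    return RegionSet(regions, genome)


def save_regions(rs: RegionSet, path: Union[str, os.PathLike]) -> None:
    """Write a RegionSet as BED; round-trips exactly through load_regions."""
    any_name = any(r.name is not None for r in rs)
    any_score = any(r.score is not None for r in rs)
    with open(path, "w") as fh:
        for r in rs:
            cols = [r.chrom, str(r.start), str(r.end)]
            if any_name or any_score:
                cols.append(r.name if r.name is not None else ".")
            if any_score:
                cols.append(repr(r.score) if r.score is not None else ".")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

def load_track(path: Union[str, os.PathLike], genome: Genome) -> BinnedTrack:
    """Read a bedGraph (or, with pyBigWig installed, a .bw/.bigwig) file.

    Intervals need not align to bin boundaries: a bin's value is the
    coverage-weighted mean over the bin's extent, with uncovered bases
    contributing zero.  Overlapping bedGraph intervals are ambiguous and
    raise an error.
    """
    path = os.fspath(path)
    if path.endswith((".bw", ".bigwig", ".bigWig")):
        return _load_track_bigwig(path, genome)

    rows: List[tuple] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise BedParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom = fields[0]
        if chrom not in genome:
            raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise BedParseError(f"{path}:{lineno}: malformed interval") from exc
        if not (0 <= start < end <= genome.length(chrom)):
            raise BedParseError(f"{path}:{lineno}: interval out of bounds")
        if value < 0 or not np.isfinite(value):
            raise BedParseError(f"{path}:{lineno}: invalid value {fields[3]}")
        rows.append((chrom, start, end, value))

    rows.sort(key=lambda t: (t[0], t[1]))
    w = genome.bin_width
    values = {c: np.zeros(genome.n_bins(c)) for c in genome.chroms}
    prev_chrom, prev_end = None, 0
    for chrom, start, end, value in rows:
        if chrom == prev_chrom and start < prev_end:
            raise BedParseError(
                f"{path}: overlapping bedGraph intervals on {chrom} near {start}"
            )
        prev_chrom, prev_end = chrom, end
        arr = values[chrom]
        b0, b1 = start // w, (end - 1) // w
        for b in (b0, b1) if b1 > b0 else (b0,):
            span_lo, span_hi = genome.bin_span(chrom, b)
            overlap = min(end, span_hi) - max(start, span_lo)
            arr[b] += value * (overlap / (span_hi - span_lo))
        if b1 > b0 + 1:
            arr[b0 + 1 : b1] += value  # fully covered interior bins
    return BinnedTrack(genome, values, validate=False)


def _load_track_bigwig(path: str, genome: Genome) -> BinnedTrack:
    try:
        import pyBigWig
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading bigwig tracks requires pyBigWig") from exc
    values: Dict[str, np.ndarray] = {}
    with pyBigWig.open(path) as bw:
        for chrom in genome.chroms:
            n = genome.length(chrom)
            per_base = np.nan_to_num(
                np.asarray(bw.values(chrom, 0, n), dtype=float), nan=0.0
            )
            nb = genome.n_bins(chrom)
            edges = np.arange(0, nb * genome.bin_width, genome.bin_width)
            sums = np.add.reduceat(per_base, edges)
            spans = np.minimum(edges + genome.bin_width, n) - edges
            values[chrom] = sums / spans
    return BinnedTrack(genome, values, validate=False)


def save_track(track: BinnedTrack, path: Union[str, os.PathLike]) -> None:
    """Write a bedGraph with runs of equal-valued bins merged; zero bins are
    implicit (omitted)."""
    genome = track.genome
    w = genome.bin_width
    with open(path, "w") as fh:
        for chrom in genome.chroms:
            v = track.values[chrom]
            if v.size == 0:
                continue
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            length = genome.length(chrom)
            for b0, b1 in zip(starts, ends):
                val = v[b0]
                if val == 0:
                    continue
                fh.write(f"{chrom}\t{b0 * w}\t{min(b1 * w, length)}\t{float(val)!r}\n")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def load_genes(path: Union[str, os.PathLike], genome: Optional[Genome] = None) -> List[GeneModel]:
    """Read gene models from BED12 or the six-column gene table.

    The table format has a header line ``gene_id chrom strand tss body
    exons`` with ``body`` as ``start-end`` and ``exons`` as comma-separated
    ``start-end`` pairs.  BED12 is detected by its 12 columns.
    """
    genes: List[GeneModel] = []
    with open(path) as fh:
        first = fh.readline()
    header = first.split("\t") if "\t" in first else first.split()
    is_table = header and header[0] == "gene_id"

    for lineno, fields in _data_lines(path):
        if is_table and fields[0] == "gene_id":
            continue  # header
        if is_table:
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: expected 6 gene-table columns")
            gene_id, chrom, strand, tss_s, body, exons_s = fields[:6]
            start, end = (int(x) for x in body.split("-"))
            exons = tuple(
                tuple(int(x) for x in pair.split("-")) for pair in exons_s.split(",") if pair
            )
            gene = GeneModel(gene_id, chrom, strand, start, end, exons)
            if int(tss_s) != gene.tss:
                raise BedParseError(
                    f"{path}:{lineno}: tss column {tss_s} inconsistent with "
                    f"strand/body (expected {gene.tss})"
                )
        else:
            if len(fields) < 12:
                raise BedParseError(f"{path}:{lineno}: expected BED12 (12 columns)")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            gene_id, strand = fields[3], fields[5]
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            gene = GeneModel(gene_id, chrom, strand, start, end, exons)
        if genome is not None:
            if gene.chrom not in genome:
                raise BedParseError(f"{path}:{lineno}: unknown chromosome {gene.chrom!r}")
            if gene.end > genome.length(gene.chrom):
                raise BedParseError(f"{path}:{lineno}: gene exceeds chromosome bounds")
        genes.append(gene)
    return genes


def save_genes(genes: Sequence[GeneModel], path: Union[str, os.PathLike]) -> None:
    """Write gene models in the six-column gene-table format."""
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tbody\texons\n")
        for g in genes:
            exons = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.start}-{g.end}\t{exons}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def load_counts(path: Union[str, os.PathLike]) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def save_counts(df: pd.DataFrame, path: Union[str, os.PathLike]) -> None:
    df.to_csv(path, sep="\t")
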