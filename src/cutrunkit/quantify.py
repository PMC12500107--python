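"""Signal matrices, length-scaled abundance, deciles, ratio tables and TPM.

The central object is the :class:`SignalMatrix`: a regions x bins matrix of
track signal, either anchored at a reference point (peak summit, TSS) with
fixed flanks, or with each region body resampled onto a standardized number
of bins (``scale_regions`` mode) so loci of different lengths become
comparable.  Resampling is coverage-weighted and mass-conserving: the sum
of a scale-regions row equals ``n_bins`` times the per-base mean signal of
the region, which is exactly the *length-scaled abundance* used for
violin/scatter comparisons of signal between timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import BinnedTrack, GeneModel, Genome, Region, RegionSet
from .intervals import closest_feature

__all__ = [
    "SignalMatrix",
    "signal_matrix",
    "length_scaled_abundance",
    "decile_partition",
    "log2_ratio_table",
    "quadrant_fractions",
    "tpm_exonic",
    "me1_expression_table",
    "promoter_class_expression",
]

Anchors = Union[RegionSet, Sequence[GeneModel]]


@dataclass
class SignalMatrix:
    """Regions x bins matrix of track signal.

    ``flagged`` marks rows whose window ran past a chromosome edge and was
    zero-padded.  Rows of minus-strand gene anchors are reversed so that
    columns always read 5' to 3'.
    """

    ids: List[str]
    values: np.ndarray  # (n_regions, n_cols) float
    mode: str  # "reference_point" | "scale_regions"
    n_bins: int  # body bins (scale_regions) or total bins (reference_point)
    flank: int  # bp each side
    bin_width: int
    flagged: np.ndarray  # (n_regions,) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"))

    def row_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def save(self, path, meta_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t")
        if meta_path is not None:
            import json

            with open(meta_path, "w") as fh:
                json.dump(
                    {
                        "mode": self.mode,
                        "n_bins": self.n_bins,
                        "flank": self.flank,
                        "bin_width": self.bin_width,
                    },
                    fh,
                    indent=1,
                )


def _anchor_rows(anchors: Anchors) -> List[Tuple[str, str, int, int, str]]:
    """Normalize anchors to (id, chrom, start, end, strand) tuples."""
    rows = []
    if isinstance(anchors, RegionSet):
        for r in anchors:
            rows.append((r.id, r.chrom, r.start, r.end, "+"))
    else:
        for g in anchors:
            rows.append((g.gene_id, g.chrom, g.start, g.end, g.strand))
    return rows


class _PrefixIntegral:
    """Exact per-base integral of a step-function track, per chromosome."""

    def __init__(self, track: BinnedTrack):
        self.track = track
        self.w = track.genome.bin_width
        self._cum: Dict[str, np.ndarray] = {}

    def _cumulative(self, chrom: str) -> np.ndarray:
        if chrom not in self._cum:
            v = self.track.values[chrom]
            self._cum[chrom] = np.concatenate(([0.0], np.cumsum(v * float(self.w))))
        return self._cum[chrom]

    def __call__(self, chrom: str, x: np.ndarray) -> np.ndarray:
        """Integral of the track over [0, x); x may be fractional, clipped to
        the chromosome (signal outside is zero)."""
        v = self.track.values[chrom]
        cum = self._cumulative(chrom)
        length = self.track.genome.length(chrom)
        x = np.clip(np.asarray(x, dtype=float), 0.0, float(length))
        idx = np.minimum((x // self.w).astype(np.int64), v.size - 1)
        return cum[idx] + v[idx] * (x - idx * self.w)


def _resample_body(
    integral: _PrefixIntegral, chrom: str, start: int, end: int, n_bins: int
) -> np.ndarray:
    """Coverage-weighted mean signal over ``n_bins`` equal sub-segments."""
    edges = start + (end - start) * np.arange(n_bins + 1) / n_bins
    cum = integral(chrom, edges)
    seg = (end - start) / n_bins
    return np.diff(cum) / seg


def signal_matrix(
    track: BinnedTrack,
    anchors: Anchors,
    mode: str = "reference_point",
    n_bins: int = 100,
    flank: int = 2000,
) -> SignalMatrix:
    """Build a regions x bins matrix of track signal.

    ``reference_point`` rows contain the raw bins spanning
    ``[anchor - flank, anchor + flank)`` where the anchor is the region
    midpoint (or the TSS for gene anchors); ``scale_regions`` rows contain
    each body resampled to ``n_bins`` by coverage-weighted averaging with
    ``flank // bin_width`` unscaled raw bins on each side.  Minus-strand
    gene rows are reversed.  Windows running past a chromosome edge are
    zero-padded and flagged.
    """
    if mode not in ("reference_point", "scale_regions"):
        raise ValueError(f"unknown mode {mode!r}")
    genome = track.genome
    w = genome.bin_width
    if flank % w:
        raise ValueError(f"flank ({flank}) must be a multiple of bin_width ({w})")
    rows = _anchor_rows(anchors)
    if not rows:
        raise ValueError("no anchors supplied")
    fb = flank // w
    is_genes = not isinstance(anchors, RegionSet)
    integral = _PrefixIntegral(track)

    ids: List[str] = []
    out: List[np.ndarray] = []
    flagged = np.zeros(len(rows), dtype=bool)
    for i, (rid, chrom, start, end, strand) in enumerate(rows):
        nb = genome.n_bins(chrom)
        v = track.values[chrom]
        if mode == "reference_point":
            anchor = (start + end) // 2 if not is_genes else (start if strand == "+" else end)
            b = anchor // w
            lo, hi = b - fb, b + fb
            row = np.zeros(2 * fb)
            src_lo, src_hi = max(lo, 0), min(hi, nb)
            if src_lo < src_hi:
                row[src_lo - lo : src_hi - lo] = v[src_lo:src_hi]
            flagged[i] = lo < 0 or hi > nb
        else:
            body = _resample_body(integral, chrom, start, end, n_bins)
            up_lo, up_hi = start // w - fb, start // w
            dn_lo, dn_hi = -(-end // w), -(-end // w) + fb
            up = np.zeros(fb)
            dn = np.zeros(fb)
            s0, s1 = max(up_lo, 0), min(up_hi, nb)
            if s0 < s1:
                up[s0 - up_lo : s1 - up_lo] = v[s0:s1]
            s0, s1 = max(dn_lo, 0), min(dn_hi, nb)
            if s0 < s1:
                dn[s0 - dn_lo : s1 - dn_lo] = v[s0:s1]
            row = np.concatenate((up, body, dn)) if fb else body
            flagged[i] = up_lo < 0 or dn_hi > nb
        if strand == "-":
            row = row[::-1].copy()
        ids.append(rid)
        out.append(row)
    return SignalMatrix(
        ids=ids,
        values=np.vstack(out),
        mode=mode,
        n_bins=(n_bins if mode == "scale_regions" else 2 * fb),
        flank=flank,
        bin_width=w,
        flagged=flagged,
    )


def length_scaled_abundance(
    track: BinnedTrack, regions: Anchors, n_bins: int = 100
) -> pd.DataFrame:
    """Per-region signal summed after resampling the body to ``n_bins``.

    Equals ``n_bins`` x the per-base mean signal, so values are comparable
    across regions of different lengths.  Returns a DataFrame indexed by
    region/gene id with columns ``abundance`` and ``length``.
    """
    rows = _anchor_rows(regions)
    if not rows:
        raise ValueError("length-scaled abundance of an empty region set is undefined")
    for rid, _, start, end, _ in rows:
        if end <= start:
            raise ValueError(f"{rid}: zero-length region")
    sm = signal_matrix(track, regions, mode="scale_regions", n_bins=n_bins, flank=0)
    lengths = [end - start for _, _, start, end, _ in rows]
    return pd.DataFrame(
        {"abundance": sm.values.sum(axis=1), "length": lengths},
        index=pd.Index(sm.ids, name="id"),
    )


def decile_partition(table: pd.DataFrame, column: str = "abundance") -> pd.Series:
    """Assign decile labels 1-10 by ascending abundance.

    Ties are broken by id so the partition is total and deterministic;
    decile sizes differ by at most one.
    """
    n = len(table)
    if n < 10:
        raise ValueError(f"decile partition requires >= 10 entries, got {n}")
    order = sorted(range(n), key=lambda i: (table[column].iloc[i], str(table.index[i])))
    labels = np.empty(n, dtype=np.int64)
    bounds = [n * k // 10 for k in range(11)]
    for k in range(10):
        for r in range(bounds[k], bounds[k + 1]):
            labels[order[r]] = k + 1
    return pd.Series(labels, index=table.index, name="decile")


def log2_ratio_table(
    early: pd.DataFrame, late: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-region M (log2 late/early) and A (mean log2 abundance) values."""
    if not early.index.equals(late.index):
        if set(early.index) != set(late.index):
            raise ValueError("early/late abundance tables have mismatched region ids")
        late = late.loc[early.index]
    e = early["abundance"].to_numpy() + pseudocount
    l = late["abundance"].to_numpy() + pseudocount
    return pd.DataFrame(
        {"M": np.log2(l / e), "A": 0.5 * np.log2(l * e)},
        index=early.index,
    )


def quadrant_fractions(x: pd.Series, y: pd.Series) -> Dict[str, float]:
    """Fractions of regions in each sign quadrant of two log2-ratio series.

    ``up`` means strictly positive; zero counts as ``down`` so the four
    fractions always sum to one.  Supports claims like "61% of peak regions
    gained mark X while losing mark Y".
    """
    if not x.index.equals(y.index):
        raise ValueError("quadrant fractions require matched region ids")
    n = len(x)
    if n == 0:
        raise ValueError("empty input")
    xu, yu = x.to_numpy() > 0, y.to_numpy() > 0
    return {
        "x_up_y_up": float((xu & yu).sum() / n),
        "x_up_y_down": float((xu & ~yu).sum() / n),
        "x_down_y_up": float((~xu & yu).sum() / n),
        "x_down_y_down": float((~xu & ~yu).sum() / n),
    }


def tpm_exonic(counts: pd.Series, genes: Sequence[GeneModel]) -> pd.Series:
    """Transcripts-per-million from per-gene counts, exon lengths only.

    ``TPM_g = 1e6 * r_g / sum(r)`` with ``r_g = count_g / exon_kb_g``; the
    result always sums to 1e6.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in counts.index if gid not in by_id]
    if missing:
        raise KeyError(f"counts reference unknown gene(s): {missing[:3]}")
    exon_kb = np.array([by_id[gid].exon_length / 1000.0 for gid in counts.index])
    if (exon_kb <= 0).any():
        raise ValueError("all genes must have positive exon length")
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    rates = vals / exon_kb
    total = rates.sum()
    if total == 0:
        raise ValueError("all-zero counts: TPM undefined")
    return pd.Series(1e6 * rates / total, index=counts.index, name="tpm")


def me1_expression_table(
    me1: pd.DataFrame,
    tpm: pd.Series,
    genes: Sequence[GeneModel],
    k27me3_peaks: RegionSet,
    promoter_len: int = 1000,
    exclusion: int = 5000,
) -> Tuple[pd.DataFrame, float]:
    """Gene-body H3K27me1 abundance vs expression, excluding
    H3K27me3-proximal genes.

    A gene is excluded when any H3K27me3 peak lies within ``exclusion`` bp
    upstream of (or overlaps) its promoter — i.e. overlaps the strand-
    adjusted window of ``promoter_len + exclusion`` bp upstream of the TSS.
    Returns the retained (me1 abundance, TPM) pairs and their Pearson r.
    """
    genome = k27me3_peaks.genome
    window = promoter_len + exclusion
    win_regions = []
    kept_genes = []
    for g in genes:
        if g.gene_id not in me1.index or g.gene_id not in tpm.index:
            continue
        win_regions.append(g.promoter(window, genome))
        kept_genes.append(g.gene_id)
    if not kept_genes:
        return pd.DataFrame(columns=["me1", "tpm"]), float("nan")
    windows = RegionSet(win_regions, genome)
    # RegionSet sorts; recover the per-gene order via region names
    excluded_ids = {
        r.name.rsplit(":", 1)[0]
        for r, hit in zip(windows, windows.overlaps_any(k27me3_peaks))
        if hit
    } if len(k27me3_peaks) else set()
    retained = [gid for gid in kept_genes if gid not in excluded_ids]
    df = pd.DataFrame(
        {"me1": me1.loc[retained, "abundance"], "tpm": tpm.loc[retained]},
        index=pd.Index(retained, name="gene_id"),
    )
    if len(df) >= 2 and df["me1"].std() > 0 and df["tpm"].std() > 0:
        r = float(sps.pearsonr(df["me1"], df["tpm"])[0])
    else:
        r = float("nan")
    return df, r


def promoter_class_expression(
    k4_only: RegionSet,
    bivalent: RegionSet,
    diff: pd.DataFrame,
    genes: Sequence[GeneModel],
    rna_tracks: Mapping[str, BinnedTrack],
    flank: int = 2000,
    n_bins: int = 100,
    max_dist: int = 10_000,
) -> Dict[str, Dict[str, object]]:
    """RNA metagenes for promoter classes stratified by H2AK119ub dynamics.

    Six gene groups: {H3K4me3-only, bivalent} x {all, increased, unchanged},
    where the increased/unchanged status comes from the ``class`` column of
    ``diff`` (indexed by promoter-region id).  Genes are assigned to
    promoter regions by nearest gene body within ``max_dist``.  Each group
    maps to its gene ids plus one gene-body metagene :class:`SignalMatrix`
    per RNA track (2 kb default flanks).
    """
    if "class" not in diff.columns:
        raise ValueError("diff table must carry a 'class' column")

    def genes_for(regions: RegionSet, wanted: Optional[str]) -> List[GeneModel]:
        assigned: Dict[str, GeneModel] = {}
        hits = closest_feature(regions, genes, max_dist=max_dist)
        for region, (gene, _) in zip(regions, hits):
            if gene is None:
                continue
            if wanted is not None:
                if region.id not in diff.index:
                    raise KeyError(f"differential table does not cover region {region.id}")
                if diff.loc[region.id, "class"] != wanted:
                    continue
            assigned.setdefault(gene.gene_id, gene)
        return [assigned[k] for k in sorted(assigned)]

    groups: Dict[str, Dict[str, object]] = {}
    for label, regions in (("k4_only", k4_only), ("bivalent", bivalent)):
        for suffix, wanted in (("all", None), ("increased", "increased"), ("unchanged", "unchanged")):
            members = genes_for(regions, wanted) if len(regions) else []
            matrices = {
                name: signal_matrix(track, members, mode="scale_regions", n_bins=n_bins, flank=flank)
                for name, track in rna_tracks.items()
            } if members else {}
            groups[f"{label}_{suffix}"] = {
                "gene_ids": [g.gene_id for g in members],
                "matrices": matrices,
            }
    return groups
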