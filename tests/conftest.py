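"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (per-base bitmaps, all-pairs scans,
O(n^2) sups) so they stay independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cutrunkit import BinnedTrack, GeneModel, Genome, Region, RegionSet
from cutrunkit.simulate import SimulationConfig, simulate_experiment


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def small_genome() -> Genome:
    return Genome({"chr1": 100_000, "chr2": 50_000}, bin_width=50)


@pytest.fixture
def tiny_genome() -> Genome:
    return Genome({"chr1": 1_000}, bin_width=50)


@pytest.fixture(scope="session")
def default_experiment():
    """The default synthetic experiment, simulated once per session."""
    return simulate_experiment(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def lean_experiment():
    """A lighter experiment (no RNA/me1 tracks) for normalization tests."""
    cfg = SimulationConfig(seed=11, include_rna=False, include_me1=False)
    return simulate_experiment(cfg)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def random_region_set(
    rng: np.random.Generator,
    genome: Genome,
    n: int,
    max_len: int = 2_000,
) -> RegionSet:
    regions = []
    chroms = list(genome.chroms)
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, genome.length(chrom) - length))
        regions.append(Region(chrom, start, start + length))
    return RegionSet(regions, genome)


def bitmap(rs: RegionSet) -> dict:
    """Per-base boolean occupancy map of a region set."""
    out = {c: np.zeros(rs.genome.length(c), dtype=bool) for c in rs.genome.chroms}
    for r in rs:
        out[r.chrom][r.start : r.end] = True
    return out


def bitmap_to_intervals(bm: dict, genome: Genome) -> list:
    """Maximal covered intervals of a bitmap, as (chrom, start, end)."""
    out = []
    for chrom in genome.chroms:
        v = bm[chrom].astype(np.int8)
        d = np.diff(np.concatenate(([0], v, [0])))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def regions_as_tuples(rs: RegionSet) -> list:
    return [(r.chrom, r.start, r.end) for r in rs]


def brute_force_overlaps(a: RegionSet, b: RegionSet) -> np.ndarray:
    flags = np.zeros(len(a), dtype=bool)
    for i, r in enumerate(a):
        flags[i] = any(r.overlaps(s) for s in b)
    return flags


def brute_force_ks_d(x: np.ndarray, y: np.ndarray) -> float:
    """sup |ECDF1 - ECDF2| over all pooled sample points."""
    pooled = np.concatenate([x, y])
    best = 0.0
    for t in pooled:
        f1 = np.mean(x <= t)
        f2 = np.mean(y <= t)
        best = max(best, abs(f1 - f2))
    return float(best)


def brute_force_maxima(v: np.ndarray, min_height: float = 0.0) -> list:
    """O(n) neighborhood scan for the strict-left/non-strict-right rule."""
    out = []
    for i in range(1, len(v) - 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] > min_height:
            out.append(i)
    return out


def per_base_values(track: BinnedTrack, chrom: str) -> np.ndarray:
    """Expand a binned track to per-base resolution (oracle use only)."""
    genome = track.genome
    w = genome.bin_width
    n = genome.length(chrom)
    reps = np.repeat(track.values[chrom], w)[:n]
    return reps
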