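"""Parameter-recovery and calibration experiments on synthetic data.

Each function runs one self-contained experiment of the validation suite —
simulate data with known ground truth, run the corresponding stage of the
pipeline, and measure how well the truth is recovered.  They are used by
the test suite and by ``scripts/acceptance.py``, and are handy for checking
that parameter changes keep the method calibrated.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .genome import Genome, Region, RegionSet
from .intervals import (
    consensus_regions,
    intersect_regions,
    overlap_fraction,
    subtract_regions,
)
from .normalize import apply_scaling, build_blacklist, compute_scaling_factor, find_local_maxima
from .simulate import (
    SimulatedExperiment,
    SimulationConfig,
    simulate_counts_matrix,
    simulate_experiment,
    thin_track,
)
from .stats import classify_differential, ks_two_sample, moderated_t

__all__ = [
    "recovery_experiment",
    "blacklist_recovery",
    "scaling_factor_recovery",
    "blacklist_benefit",
    "cross_depth_correlation",
    "moderated_t_null_calibration",
    "moderated_t_power",
    "interval_bitmap_agreement",
    "ks_bruteforce_agreement",
]


def recovery_experiment(exp: SimulatedExperiment) -> Dict[str, float]:
    """Blacklist recovery statistics on an already-simulated experiment."""
    maxima = {
        sid: find_local_maxima(track)
        for sid, track in exp.tracks.items()
        if not sid.startswith("RNA")
    }
    bl = build_blacklist(maxima, exp.genes)
    truth = {(c, p) for c, p in exp.truth.artifact_positions}
    found = {(r.chrom, r.start) for r in bl}
    n_injected = len(truth)
    return {
        "recovered_fraction": len(truth & found) / n_injected if n_injected else 1.0,
        "false_positives": len(found - truth),
        "n_injected": n_injected,
        "blacklist_size": len(bl),
    }


def blacklist_recovery(seed: int = 1) -> Dict[str, float]:
    """Inject shared intergenic spikes at default settings and recover them."""
    cfg = SimulationConfig(seed=seed, include_rna=False, include_me1=False)
    return recovery_experiment(simulate_experiment(cfg))


def scaling_factor_recovery(n_simulations: int = 20, seed: int = 1) -> Dict[str, float]:
    """Recover planted global scale factors in [0.5, 3] on the desk genome.

    Each simulation plants one true factor between two replicates of the
    primary mark; the blacklist is rebuilt from scratch each time.
    """
    rng = np.random.default_rng(seed)
    errors = []
    for i in range(n_simulations):
        true_f = float(rng.uniform(0.5, 3.0))
        cfg = SimulationConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            include_rna=False,
            include_me1=False,
            scale_factors={"H2AK119ub_early_rep2": 1.0 / true_f},
        )
        exp = simulate_experiment(cfg)
        maxima = {sid: find_local_maxima(t) for sid, t in exp.tracks.items()}
        bl = build_blacklist(maxima, exp.genes)
        sf = compute_scaling_factor(
            exp.tracks["H2AK119ub_early_rep1"], exp.tracks["H2AK119ub_early_rep2"], bl
        )
        errors.append(abs(sf.value - true_f) / true_f)
    errors = np.asarray(errors)
    return {
        "median_relative_error": float(np.median(errors)),
        "max_relative_error": float(errors.max()),
        "n_simulations": n_simulations,
    }


def blacklist_benefit(
    seed: int = 21, true_factor: float = 1.7, n_artifacts: int = 400
) -> Dict[str, float]:
    """Factor error with vs without the blacklist under heavy contamination.

    Identical-height shared spikes drag the no-blacklist percentile ratio
    toward 1 regardless of the true depth difference; excluding them should
    restore the factor.
    """
    cfg = SimulationConfig(
        seed=seed,
        include_rna=False,
        include_me1=False,
        n_artifacts=n_artifacts,
        artifact_multiplier=10.0,
        scale_factors={"H2AK119ub_early_rep2": 1.0 / true_factor},
    )
    exp = simulate_experiment(cfg)
    maxima = {sid: find_local_maxima(t) for sid, t in exp.tracks.items()}
    # heavier contamination: candidate threshold must sit below the spike
    # heights, so a lower quantile with recurrence doing the filtering
    bl = build_blacklist(maxima, exp.genes, height_quantile=0.95)
    ref = exp.tracks["H2AK119ub_early_rep1"]
    tgt = exp.tracks["H2AK119ub_early_rep2"]
    with_bl = compute_scaling_factor(ref, tgt, bl).value
    without_bl = compute_scaling_factor(ref, tgt, None).value
    return {
        "error_with_blacklist": abs(with_bl - true_factor) / true_factor,
        "error_without_blacklist": abs(without_bl - true_factor) / true_factor,
        "true_factor": true_factor,
    }


def cross_depth_correlation(seed: int = 7, keep_fraction: float = 0.25) -> Dict[str, float]:
    """Thin one sample binomially, renormalize, and correlate maxima heights."""
    cfg = SimulationConfig(
        seed=seed, include_rna=False, include_me1=False, n_artifacts=0, scale_factors={}
    )
    exp = simulate_experiment(cfg)
    full = exp.tracks["H2AK119ub_early_rep1"]
    thin = thin_track(full, keep_fraction, np.random.default_rng(seed))
    sf = compute_scaling_factor(full, thin)
    scaled = apply_scaling(thin, sf)
    lm = find_local_maxima(full)
    h_full = lm.heights
    h_thin = np.array(
        [scaled.values[c][b] for c, b in zip(lm.table["chrom"], lm.table["bin"])]
    )
    r = float(np.corrcoef(h_full, h_thin)[0, 1])
    return {"pearson_r": r, "n_maxima": len(h_full), "scaling_factor": sf.value}


def moderated_t_null_calibration(
    seed: int = 1, n_regions: int = 2000, n_per_condition: int = 4
) -> Dict[str, float]:
    """Fraction of raw p < 0.05 on the no-differential simulation."""
    matrix, _ = simulate_counts_matrix(
        n_regions=n_regions,
        n_per_condition=n_per_condition,
        frac_differential=0.0,
        seed=seed,
    )
    design = [c.rsplit("_", 1)[0] for c in matrix.columns]
    table, d0, s0_sq = moderated_t(matrix, design)
    return {
        "fraction_p_below_05": float((table["p"] < 0.05).mean()),
        "d0": d0,
        "s0_squared": s0_sq,
        "n_regions": n_regions,
    }


def moderated_t_power(
    seed: int = 1,
    n_regions: int = 2000,
    n_per_condition: int = 4,
    frac_differential: float = 0.05,
    log2fc: float = 2.0,
) -> Dict[str, float]:
    """Realized FDR and sensitivity of the full classify pipeline."""
    matrix, truth = simulate_counts_matrix(
        n_regions=n_regions,
        n_per_condition=n_per_condition,
        frac_differential=frac_differential,
        log2fc=log2fc,
        seed=seed,
    )
    design = [c.rsplit("_", 1)[0] for c in matrix.columns]
    table, _, _ = moderated_t(matrix, design)
    classified = classify_differential(table)
    called = classified["class"] != "unchanged"
    is_diff = truth["is_differential"]
    n_called = int(called.sum())
    tp = int((called & is_diff).sum())
    fp = n_called - tp
    return {
        "fdr": fp / n_called if n_called else 0.0,
        "sensitivity": tp / int(is_diff.sum()) if is_diff.any() else 1.0,
        "n_called": n_called,
        "n_true": int(is_diff.sum()),
    }


def _bitmap_intervals(regions: RegionSet, genome: Genome) -> Dict[str, np.ndarray]:
    out = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.chroms}
    for r in regions:
        out[r.chrom][r.start : r.end] = True
    return out


def interval_bitmap_agreement(
    n_instances: int = 200, genome_size: int = 100_000, seed: int = 1
) -> Dict[str, float]:
    """Check the interval algebra against a naive per-base bitmap oracle.

    Returns the fraction of randomized instances on which intersect,
    subtract, consensus, and overlap_fraction all agree with brute force.
    """
    rng = np.random.default_rng(seed)
    genome = Genome({"chr1": genome_size}, bin_width=50)
    agree = 0
    for _ in range(n_instances):
        sets = []
        for _ in range(3):
            regions = []
            for _ in range(int(rng.integers(5, 50))):
                length = int(rng.integers(1, 2_000))
                start = int(rng.integers(0, genome_size - length))
                regions.append(Region("chr1", start, start + length))
            sets.append(RegionSet(regions, genome))
        a, b, c = sets
        bm = [_bitmap_intervals(s, genome) for s in sets]

        ok = True
        inter = intersect_regions(a, b)
        expected = bm[0]["chr1"] & bm[1]["chr1"]
        got = _bitmap_intervals(inter, genome)["chr1"]
        ok &= bool(np.array_equal(expected, got))
        # maximality: merged output, one interval per covered run
        ok &= len(inter) == _run_count(expected)

        cons = consensus_regions([a, b, c])
        expected3 = bm[0]["chr1"] & bm[1]["chr1"] & bm[2]["chr1"]
        ok &= bool(np.array_equal(expected3, _bitmap_intervals(cons, genome)["chr1"]))

        sub = subtract_regions(a, b)
        keep = [
            not (bm[1]["chr1"][r.start : r.end]).any() for r in a
        ]
        expected_sub = [(r.chrom, r.start, r.end) for r, k in zip(a, keep) if k]
        ok &= [(r.chrom, r.start, r.end) for r in sub] == expected_sub

        fa, fb = overlap_fraction(a, b)
        bf_a = np.mean([bm[1]["chr1"][r.start : r.end].any() for r in a])
        bf_b = np.mean([bm[0]["chr1"][r.start : r.end].any() for r in b])
        ok &= abs(fa - bf_a) < 1e-12 and abs(fb - bf_b) < 1e-12

        agree += bool(ok)
    return {"agreement_fraction": agree / n_instances, "n_instances": n_instances}


def _run_count(mask: np.ndarray) -> int:
    d = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    return int((d == 1).sum())


def ks_bruteforce_agreement(n_pairs: int = 100, seed: int = 1) -> Dict[str, float]:
    """Max |D - brute-force sup over pooled points| over random sample pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        n1, n2 = int(rng.integers(5, 200)), int(rng.integers(5, 200))
        x = rng.normal(0, 1, n1)
        y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n2)
        res = ks_two_sample(x, y)
        pooled = np.concatenate([x, y])
        brute = max(abs(np.mean(x <= t) - np.mean(y <= t)) for t in pooled)
        worst = max(worst, abs(res.D - brute))
    return {"max_abs_difference": worst, "n_pairs": n_pairs}
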