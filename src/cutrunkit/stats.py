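"""Statistical comparisons: K-S tests, blacklist-filtered Pearson matrices,
empirical-Bayes moderated-t differential abundance, and PCA.

The differential-abundance machinery follows the empirical-Bayes moderated
t-statistic: per-region sample variances ``s_g^2`` on ``d`` residual df are
assumed to follow a scaled inverse-chi-square prior with df ``d0`` and
scale ``s0^2``; the posterior variance is

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated statistic ``t_g = log2FC_g / (s~_g * sqrt(1/n1 + 1/n2))``
is referred to a t distribution on ``d0 + d`` degrees of freedom.  The
hyperparameters ``(d0, s0^2)`` are fitted by moment matching of the scaled
F/inverse-chi-square model on ``log s_g^2`` (digamma/trigamma matching).
At ``d0 = 0`` the statistic reduces exactly to the classical two-sample
pooled-variance t; as ``d0 -> inf`` all variances shrink to the common
``s0^2``.

The model is exposed statsmodels-style: build
:class:`DifferentialAbundance` from a regions x samples log2 matrix plus a
condition design, ``fit()`` it, and read estimates, moderated statistics,
adjusted p-values, and the three-class labelling off the returned
:class:`DifferentialResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .genome import BinnedTrack, RegionSet, _check_same_genome

__all__ = [
    "KSResult",
    "ks_two_sample",
    "pearson_tracks",
    "CorrelationMatrix",
    "correlation_matrix",
    "fit_variance_prior",
    "moderated_t",
    "bh_adjust",
    "classify_differential",
    "DifferentialAbundance",
    "DifferentialResults",
    "pca_variance_explained",
]


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSResult:
    """Two-sample K-S comparison: D = sup |ECDF1 - ECDF2|."""

    D: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test with the asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("K-S test requires non-empty samples")
    res = sps.ks_2samp(x, y, method="asymp")
    return KSResult(D=float(res.statistic), p_value=float(res.pvalue), n1=x.size, n2=y.size)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _usable_bins(
    track: BinnedTrack,
    blacklist: Optional[RegionSet],
    mask: Optional[RegionSet],
) -> np.ndarray:
    keep_parts = []
    bl = blacklist.bin_mask() if blacklist is not None and len(blacklist) else None
    mk = mask.bin_mask() if mask is not None else None
    for chrom in track.genome.chroms:
        n = track.genome.n_bins(chrom)
        keep = np.ones(n, dtype=bool)
        if bl is not None:
            keep &= ~bl[chrom]
        if mk is not None:
            keep &= mk[chrom]
        keep_parts.append(keep)
    return np.concatenate(keep_parts)


def pearson_tracks(
    a: BinnedTrack,
    b: BinnedTrack,
    blacklist: Optional[RegionSet] = None,
    mask: Optional[RegionSet] = None,
) -> float:
    """Pearson r over bins outside the blacklist (and inside ``mask`` when a
    region mask is given).  Bins where both tracks are zero are retained."""
    _check_same_genome(a, b)
    keep = _usable_bins(a, blacklist, mask)
    va, vb = a.flat()[keep], b.flat()[keep]
    if va.size < 2:
        raise ValueError("fewer than 2 usable bins after filtering")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in filtered bins; correlation undefined")
    return float(np.corrcoef(va, vb)[0, 1])


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson matrix with mask provenance."""

    table: pd.DataFrame
    blacklist_size: int = 0
    masked: bool = False

    @property
    def sample_ids(self) -> List[str]:
        return list(self.table.index)

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def correlation_matrix(
    tracks: Mapping[str, BinnedTrack],
    blacklist: Optional[RegionSet] = None,
    mask: Optional[RegionSet] = None,
) -> CorrelationMatrix:
    """All pairwise blacklist-filtered Pearson correlations between tracks."""
    ids = list(tracks)
    if len(ids) < 2:
        raise ValueError("correlation matrix requires >= 2 tracks")
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = pearson_tracks(tracks[ids[i]], tracks[ids[j]], blacklist, mask)
            mat[i, j] = mat[j, i] = r
    return CorrelationMatrix(
        table=pd.DataFrame(mat, index=ids, columns=ids),
        blacklist_size=0 if blacklist is None else len(blacklist),
        masked=mask is not None,
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment-match the scaled inverse-chi-square prior on ``log s^2``.

    Given per-region sample variances on ``df`` residual degrees of
    freedom, returns ``(d0, s0_squared)``.  ``d0 = inf`` (with ``s0^2`` the
    common value) when the observed spread of ``log s^2`` is no larger than
    the chi-square sampling spread alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    matrix: pd.DataFrame,
    design: Sequence[str],
    d0: Optional[float] = None,
) -> Tuple[pd.DataFrame, float, float]:
    """Per-region moderated t-statistics for a two-condition comparison.

    ``matrix`` is regions x samples of log2 values; ``design`` gives one
    condition label per column (exactly two distinct labels, each with >= 2
    samples).  The log2 fold change is second condition minus first, in
    order of first appearance.  Pass ``d0`` to override the fitted prior df
    (0 recovers the classical pooled t; ``inf`` the common-variance
    statistic).

    Returns ``(table, d0, s0_squared)`` where the table has columns
    ``mean_<cond1>``, ``mean_<cond2>``, ``log2fc``, ``t``, ``p`` and ``df``.
    """
    design = list(design)
    if len(design) != matrix.shape[1]:
        raise ValueError("design length must match the number of sample columns")
    cond_order = list(dict.fromkeys(design))
    if len(cond_order) != 2:
        raise ValueError(f"exactly two conditions required, got {cond_order}")
    g1 = [i for i, c in enumerate(design) if c == cond_order[0]]
    g2 = [i for i, c in enumerate(design) if c == cond_order[1]]
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs >= 2 samples")
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 regions")

    x = matrix.to_numpy(dtype=float)
    m1 = x[:, g1].mean(axis=1)
    m2 = x[:, g2].mean(axis=1)
    lfc = m2 - m1
    d = n1 + n2 - 2
    ss = ((x[:, g1] - m1[:, None]) ** 2).sum(axis=1) + ((x[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    if d0 is None:
        d0, s0_sq = fit_variance_prior(s2, d)
    else:
        d0 = float(d0)
        _, s0_sq = fit_variance_prior(s2, d) if d0 > 0 else (None, 0.0)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    # zero-variance, zero-difference regions: t = 0, p = 1 by convention
    degenerate = (se == 0) & (lfc == 0)
    with np.errstate(invalid="ignore"):
        t = np.where((se == 0) & (lfc != 0), np.sign(lfc) * np.inf, t)
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.where(degenerate, 1.0, p)
    t = np.where(degenerate, 0.0, t)

    table = pd.DataFrame(
        {
            f"mean_{cond_order[0]}": m1,
            f"mean_{cond_order[1]}": m2,
            "log2fc": lfc,
            "t": t,
            "p": p,
            "df": np.full(len(lfc), df_total),
        },
        index=matrix.index,
    )
    return table, float(d0), float(s0_sq)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, rank-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_differential(
    table: pd.DataFrame,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.DataFrame:
    """Three-class labelling of a moderated-t table.

    ``increased`` iff adjusted p < alpha and fold change >= fc_threshold
    (i.e. log2fc >= log2(fc_threshold)); ``decreased`` symmetric; otherwise
    ``unchanged``.  Adds ``adj_p`` and ``class`` columns; the attached
    ``.attrs['summary']`` records counts and percentages.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    out = table.copy()
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    lfc_cut = np.log2(fc_threshold)
    sig = out["adj_p"] < alpha
    cls = np.where(
        sig & (out["log2fc"] >= lfc_cut),
        "increased",
        np.where(sig & (out["log2fc"] <= -lfc_cut), "decreased", "unchanged"),
    )
    out["class"] = cls
    n = len(out)
    n_up = int((cls == "increased").sum())
    n_down = int((cls == "decreased").sum())
    out.attrs["summary"] = {
        "total": n,
        "increased": n_up,
        "decreased": n_down,
        "unchanged": n - n_up - n_down,
        "pct_increased": round(100.0 * n_up / n, 1) if n else 0.0,
        "pct_decreased": round(100.0 * n_down / n, 1) if n else 0.0,
    }
    return out


class DifferentialAbundance:
    """Empirical-Bayes differential-abundance model for log2 region signal.

    Parameters
    ----------
    data
        Regions x samples DataFrame of log2-scale values (e.g. log2 of
        length-scaled abundance or of normalized counts per consensus peak).
    design
        One condition label per sample column; exactly two conditions.

    Examples
    --------
    >>> model = DifferentialAbundance(matrix, ["early"] * 4 + ["late"] * 4)
    >>> res = model.fit()
    >>> res.classify(alpha=0.05, fc_threshold=1.5)["class"].value_counts()
    """

    def __init__(self, data: pd.DataFrame, design: Sequence[str]):
        self.data = data
        self.design = list(design)

    @classmethod
    def from_abundances(
        cls,
        abundances: Mapping[str, pd.DataFrame],
        design: Mapping[str, str],
        pseudocount: float = 1.0,
    ) -> "DifferentialAbundance":
        """Assemble the log2 matrix from per-sample abundance tables."""
        cols = {
            sid: np.log2(tab["abundance"].to_numpy() + pseudocount)
            for sid, tab in abundances.items()
        }
        first = next(iter(abundances.values()))
        data = pd.DataFrame(cols, index=first.index)
        return cls(data, [design[sid] for sid in data.columns])

    def fit(self, d0: Optional[float] = None) -> "DifferentialResults":
        table, d0_hat, s0_sq = moderated_t(self.data, self.design, d0=d0)
        return DifferentialResults(self, table, d0_hat, s0_sq)


@dataclass
class DifferentialResults:
    """Fit results: per-region estimates plus the variance-prior fit."""

    model: DifferentialAbundance
    table: pd.DataFrame
    d0: float
    s0_squared: float

    def classify(self, alpha: float = 0.05, fc_threshold: float = 1.5) -> pd.DataFrame:
        return classify_differential(self.table, alpha=alpha, fc_threshold=fc_threshold)

    def summary(self, alpha: float = 0.05, fc_threshold: float = 1.5) -> str:
        cls = self.classify(alpha=alpha, fc_threshold=fc_threshold)
        s = cls.attrs["summary"]
        cond = [c for c in dict.fromkeys(self.model.design)]
        lines = [
            "Differential abundance (empirical-Bayes moderated t)",
            "====================================================",
            f"regions: {s['total']}    samples: {len(self.model.design)} "
            f"({cond[0]} vs {cond[1]})",
            f"prior df (d0): {self.d0:.4g}    prior variance (s0^2): {self.s0_squared:.4g}",
            f"thresholds: adjusted p < {alpha}, fold change >= {fc_threshold}",
            f"increased: {s['increased']} ({s['pct_increased']}%)",
            f"decreased: {s['decreased']} ({s['pct_decreased']}%)",
            f"unchanged: {s['unchanged']}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_variance_explained(matrix: Union[np.ndarray, pd.DataFrame]) -> np.ndarray:
    """Variance fractions of the principal components of samples x features
    data (columns centered); fractions sum to 1 over all components."""
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PCA requires a 2-D matrix with >= 2 samples")
    if x.shape[1] < 1:
        raise ValueError("PCA requires >= 1 feature")
    xc = x - x.mean(axis=0, keepdims=True)
    s = np.linalg.svd(xc, compute_uv=False)
    total = (s**2).sum()
    if total == 0:
        raise ValueError("zero total variance")
    return s**2 / total
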