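"""Summary statistics: PSI correlations, MDS, organ co-occurrence, flank
score aggregation, MAF comparison and binomial confidence intervals."""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "binomial_ci",
    "maf_compare",
    "mds_embed",
    "mean_flank_score",
    "organ_pair_cooccurrence",
    "pairwise_correlation",
    "psi_distance_matrix",
]

#: Sentinel used when a co-occurrence odds ratio is infinite.
OR_INF_SENTINEL = float("inf")


def pairwise_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r over pairwise-complete entries; NaN when fewer than 3 pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        return math.nan
    return float(stats.pearsonr(x[mask], y[mask])[0])


def psi_distance_matrix(psi: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - r distances between the columns (samples) of a PSI matrix."""
    samples = list(psi.columns)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = pairwise_correlation(psi.iloc[:, i], psi.iloc[:, j])
            d[i, j] = d[j, i] = 1.0 - r
    return pd.DataFrame(d, index=samples, columns=samples)


def mds_embed(distances: np.ndarray | pd.DataFrame, k: int = 2) -> np.ndarray:
    """Classical (principal-coordinates) multidimensional scaling.

    Double-centers the squared-distance matrix, takes the top ``k``
    eigenpairs and scales eigenvectors by the square root of their
    eigenvalues; negative eigenvalues are truncated at zero.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[idx], 0.0, None)
    return evecs[:, idx] * np.sqrt(lam)


def organ_pair_cooccurrence(membership: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Fisher tests of devAS co-occurrence for all organ pairs.

    ``membership`` is a boolean exon x organ table; only exons that are
    devAS in at least one organ are included.  Returns one row per
    unordered organ pair with the 2x2 table, odds ratio (infinite ratios
    reported as ``inf``) and two-sided Fisher p.
    """
    mem = membership.astype(bool)
    mem = mem.loc[mem.any(axis=1)]
    organs = list(mem.columns)
    rows = []
    for i, a in enumerate(organs):
        for b in organs[i + 1 :]:
            va, vb = mem[a].to_numpy(), mem[b].to_numpy()
            n11 = int(np.sum(va & vb))
            n10 = int(np.sum(va & ~vb))
            n01 = int(np.sum(~va & vb))
            n00 = int(np.sum(~va & ~vb))
            degenerate = (n11 + n10 == 0 or n01 + n00 == 0
                          or n11 + n01 == 0 or n10 + n00 == 0)
            if degenerate:
                odds, p = math.nan, 1.0
            else:
                odds, p = stats.fisher_exact(
                    [[n11, n10], [n01, n00]], alternative="two-sided"
                )
                odds = OR_INF_SENTINEL if math.isinf(odds) else float(odds)
            rows.append(
                {
                    "organ_a": a,
                    "organ_b": b,
                    "n11": n11,
                    "n10": n10,
                    "n01": n01,
                    "n00": n00,
                    "odds_ratio": odds,
                    "p": float(p),
                }
            )
    return pd.DataFrame(rows)


def mean_flank_score(tracks: np.ndarray) -> pd.DataFrame:
    """Positionwise mean and 2 x s.e.m. over a set of per-base score tracks.

    ``tracks`` is exons x positions; NaN entries are excluded per
    position.  Raises on an empty set.
    """
    tracks = np.asarray(tracks, dtype=float)
    if tracks.ndim != 2 or tracks.shape[0] == 0:
        raise ValueError("non-empty exons x positions array required")
    n = np.sum(~np.isnan(tracks), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(tracks, axis=0)
        sd = np.nanstd(tracks, axis=0, ddof=1) if tracks.shape[0] > 1 else np.zeros(
            tracks.shape[1]
        )
    sem = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return pd.DataFrame(
        {"position": np.arange(tracks.shape[1]), "mean": mean, "sem2": 2.0 * sem}
    )


def maf_compare(
    group_a: pd.DataFrame, group_b: pd.DataFrame
) -> dict[str, float]:
    """Compare minor-allele frequencies of two SNP sets.

    Each table needs ``minor_count`` and ``total_alleles`` columns.
    Singletons (minor allele count <= 1) are removed; the statistic is the
    mean log10(MAF) per group plus a two-sided Mann-Whitney U p-value.
    """
    def mafs(df: pd.DataFrame) -> np.ndarray:
        keep = df["minor_count"] > 1
        sub = df.loc[keep]
        return (sub["minor_count"] / sub["total_alleles"]).to_numpy(dtype=float)

    ma, mb = mafs(group_a), mafs(group_b)
    if ma.size == 0 or mb.size == 0:
        return {
            "mean_log10_maf_a": math.nan,
            "mean_log10_maf_b": math.nan,
            "p": math.nan,
            "n_a": int(ma.size),
            "n_b": int(mb.size),
        }
    p = float(stats.mannwhitneyu(ma, mb, alternative="two-sided").pvalue)
    return {
        "mean_log10_maf_a": float(np.mean(np.log10(ma))),
        "mean_log10_maf_b": float(np.mean(np.log10(mb))),
        "p": p,
        "n_a": int(ma.size),
        "n_b": int(mb.size),
    }


def binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact confidence interval for a binomial proportion."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n >= 1")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper
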