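"""Detection of developmentally dynamic AS (devAS) with quasi-binomial GLMs.

Per segment, species and organ, inclusion/exclusion counts are modeled as
``(i, e) ~ a + a^2 + a^3`` where ``a`` is the natural logarithm of the
developmental age in days from conception (postnatal ages are offset by the
species gestation time).  The binomial-mean model is fitted by IRLS with a
logit link; each polynomial term is tested with an F-test comparing
quasi-deviances of the full model and the model with that term removed,
using the Pearson dispersion of the full model (denominator df = n - 4).
Term p-values are adjusted with Benjamini-Hochberg, pooled across all terms
of all eligible segments within one species-organ analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GESTATION_DAYS",
    "DevASTestResult",
    "add_log_age",
    "bh_adjust",
    "eligibility",
    "fit_devas_glm",
    "run_devas",
]

#: Typical gestation times in days.
GESTATION_DAYS = {
    "human": 280,
    "macaque": 165,
    "mouse": 20,
    "rat": 21,
    "rabbit": 30,
    "opossum": 15,
    "chicken": 21,
}

_N_MEAN_PARAMS = 4  # intercept + a + a^2 + a^3


def add_log_age(
    meta: pd.DataFrame, gestation: dict[str, float] | None = None
) -> pd.DataFrame:
    """Return metadata with ``days_post_conception`` and log-age column ``a``.

    If ``days_post_conception`` is absent it is derived as
    ``postnatal_days + gestation[species]``.
    """
    gestation = GESTATION_DAYS if gestation is None else gestation
    out = meta.copy()
    if "days_post_conception" not in out.columns:
        out["days_post_conception"] = out["postnatal_days"] + out["species"].map(
            gestation
        )
    if (out["days_post_conception"] <= 0).any():
        raise ValueError("days_post_conception must be positive")
    out["a"] = np.log(out["days_post_conception"].astype(float))
    return out


def eligibility(
    totals: Sequence[float],
    psis: Sequence[float],
    min_coverage: int = 10,
    min_coverage_frac: float = 0.6,
    min_in_range: int = 4,
    psi_range: tuple[float, float] = (0.1, 0.9),
) -> bool:
    """Segment is testable iff coverage and informative-PSI conditions hold.

    ``totals`` are i+e per sample of the organ; ``psis`` the defined PSI
    values (NaN allowed, ignored).  Requires i+e >= ``min_coverage`` in at
    least ``min_coverage_frac`` of samples and at least ``min_in_range``
    defined PSI values inside ``psi_range`` (inclusive).
    """
    totals = np.asarray(totals, dtype=float)
    if totals.size == 0:
        raise ValueError("at least one sample required")
    covered = np.mean(totals >= min_coverage)
    if covered < min_coverage_frac:
        return False
    psis = np.asarray(psis, dtype=float)
    ok = np.sum(
        (~np.isnan(psis)) & (psis >= psi_range[0]) & (psis <= psi_range[1])
    )
    return bool(ok >= min_in_range)


@dataclass
class DevASTestResult:
    segment_id: str
    organ: str
    p_values: dict[str, float] = field(default_factory=dict)  # term -> p
    deviance_drops: dict[str, float] = field(default_factory=dict)
    dispersion: float = math.nan
    converged: bool = True
    n_samples: int = 0
    adjusted: dict[str, float] = field(default_factory=dict)

    @property
    def padj_min(self) -> float:
        return min(self.adjusted.values()) if self.adjusted else math.nan

    @property
    def significant(self) -> bool:
        return bool(self.adjusted) and self.padj_min < 0.05


def _binomial_deviance(i: np.ndarray, e: np.ndarray, p: np.ndarray) -> float:
    n = i + e
    with np.errstate(divide="ignore", invalid="ignore"):
        ti = np.where(i > 0, i * np.log(i / (n * p)), 0.0)
        te = np.where(e > 0, e * np.log(e / (n * (1.0 - p))), 0.0)
    return float(2.0 * np.sum(ti + te))


def _fit_binomial_irls(
    X: np.ndarray,
    i: np.ndarray,
    e: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, float, float, bool]:
    """Logit-link binomial IRLS; returns (beta, deviance, pearson chi2, converged)."""
    n = i + e
    y = i / n
    # initialize from empirical logits with a continuity correction
    eta = np.log((i + 0.5) / (e + 0.5))
    beta = np.zeros(X.shape[1])
    dev = math.inf
    converged = False
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-10, 1.0 - 1e-10)
        w = n * p * (1.0 - p)
        z = eta + (y - p) / (p * (1.0 - p))
        wx = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ wx, wx.T @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(X * np.sqrt(w)[:, None], z * np.sqrt(w), rcond=None)[0]
        eta = X @ beta_new
        # cap the linear predictor against separation blow-up
        eta = np.clip(eta, -30.0, 30.0)
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1.0 - 1e-10)
        dev_new = _binomial_deviance(i, e, p)
        delta = abs(dev - dev_new)
        beta, dev = beta_new, dev_new
        if delta < tol * (abs(dev_new) + 0.1):
            converged = True
            break
    p = np.clip(1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30))), 1e-10, 1 - 1e-10)
    pearson = float(np.sum((i - n * p) ** 2 / (n * p * (1.0 - p))))
    return beta, dev, pearson, converged


def fit_devas_glm(
    i: Sequence[float], e: Sequence[float], a: Sequence[float], organ: str = "", segment_id: str = ""
) -> DevASTestResult:
    """Fit the cubic-age quasi-binomial model and test each polynomial term.

    Samples with i + e = 0 are dropped.  Requires at least 6 informative
    samples (4 mean parameters plus dispersion).
    """
    i = np.asarray(i, dtype=float)
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    keep = (i + e) > 0
    i, e, a = i[keep], e[keep], a[keep]
    n = i.size
    if n < 6:
        raise ValueError("at least 6 samples with i+e>0 required")
    # center/scale the age axis for numerical conditioning; the polynomial
    # span (and hence deviances and tests) is invariant to this
    a0 = (a - a.mean()) / (a.std() if a.std() > 0 else 1.0)
    X = np.column_stack([np.ones(n), a0, a0**2, a0**3])
    res = DevASTestResult(segment_id=segment_id, organ=organ, n_samples=n)
    try:
        _, dev_full, pearson, converged = _fit_binomial_irls(X, i, e)
    except Exception:
        res.converged = False
        return res
    df_resid = n - _N_MEAN_PARAMS
    phi = pearson / df_resid
    res.dispersion = phi
    res.converged = converged
    if not converged:
        return res
    for k, term in zip((1, 2, 3), ("a", "a2", "a3")):
        Xr = np.delete(X, k, axis=1)
        try:
            _, dev_red, _, conv_r = _fit_binomial_irls(Xr, i, e)
        except Exception:
            conv_r = False
        if not conv_r:
            res.converged = False
            continue
        delta = max(dev_red - dev_full, 0.0)
        res.deviance_drops[term] = delta
        if delta <= 1e-12:
            p = 1.0
        elif phi <= 1e-300:
            p = 0.0
        else:
            f = delta / phi
            p = float(stats.f.sf(f, 1, df_resid))
        res.p_values[term] = p
    return res


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def run_devas(
    counts: pd.DataFrame,
    psi: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.05,
    min_coverage: int = 10,
    min_coverage_frac: float = 0.6,
    min_in_range: int = 4,
    psi_range: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Run eligibility + GLM + BH for every segment in every species-organ.

    Parameters
    ----------
    counts:
        Long table (segment_id, sample_id, i, e).
    psi:
        Segments x samples PSI matrix (NaN = undefined).
    meta:
        Sample metadata with sample_id, species, organ and log-age ``a``
        (see :func:`add_log_age`).

    Returns a table with one row per tested segment: per-term raw and
    BH-adjusted p-values (adjusted jointly across all terms of all tested
    segments within the species-organ analysis), dispersion and the
    significance call.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    wide_i = counts.pivot_table(index="segment_id", columns="sample_id", values="i")
    wide_e = counts.pivot_table(index="segment_id", columns="sample_id", values="e")
    rows = []
    for (species, organ), sub in meta.groupby(["species", "organ"], sort=True):
        samples = [s for s in sub.index if s in wide_i.columns]
        if not samples:
            continue
        ages = sub.loc[samples, "a"].to_numpy(dtype=float)
        fits: list[DevASTestResult] = []
        for seg in wide_i.index:
            iv = wide_i.loc[seg, samples].to_numpy(dtype=float)
            ev = wide_e.loc[seg, samples].to_numpy(dtype=float)
            mask = ~(np.isnan(iv) | np.isnan(ev))
            iv, ev, av = iv[mask], ev[mask], ages[mask]
            if iv.size == 0:
                continue
            psis = (
                psi.loc[seg, np.asarray(samples)[mask]].to_numpy(dtype=float)
                if seg in psi.index
                else np.full(iv.size, np.nan)
            )
            if not eligibility(
                iv + ev,
                psis,
                min_coverage=min_coverage,
                min_coverage_frac=min_coverage_frac,
                min_in_range=min_in_range,
                psi_range=psi_range,
            ):
                continue
            if np.sum((iv + ev) > 0) < 6:
                continue
            fit = fit_devas_glm(iv, ev, av, organ=organ, segment_id=seg)
            fits.append(fit)
        # pool all term p-values of this species-organ analysis for BH
        keys = [(f, t) for f in fits for t in sorted(f.p_values)]
        if keys:
            adj = bh_adjust([f.p_values[t] for f, t in keys])
            for (f, t), q in zip(keys, adj):
                f.adjusted[t] = float(q)
        for f in fits:
            rows.append(
                {
                    "segment_id": f.segment_id,
                    "species": species,
                    "organ": organ,
                    "p_a": f.p_values.get("a", math.nan),
                    "p_a2": f.p_values.get("a2", math.nan),
                    "p_a3": f.p_values.get("a3", math.nan),
                    "padj_a": f.adjusted.get("a", math.nan),
                    "padj_a2": f.adjusted.get("a2", math.nan),
                    "padj_a3": f.adjusted.get("a3", math.nan),
                    "padj_min": f.padj_min,
                    "dispersion": f.dispersion,
                    "n_samples": f.n_samples,
                    "converged": f.converged,
                    "significant": bool(f.adjusted) and f.padj_min < alpha,
                }
            )
    return pd.DataFrame(rows)
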