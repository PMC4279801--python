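"""Moderated-t differential expression per strain x time contrast.

Each contrast tests one strain and time point against its time-0
reference using the replicate log2 ratios: a one-sample linear fit per
gene (mean, sample variance), empirical-Bayes variance moderation
(gene-wise variances shrunk towards a prior estimated from their
distribution), two-sided p-values on the augmented degrees of freedom,
Benjamini-Hochberg adjustment within the contrast and selection at
FDR <= 5% with |log2 fold change| > 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from lactokin.config import AnalysisThresholds
from lactokin.microarray import split_replicate_column

logger = logging.getLogger(__name__)

__all__ = [
    "fit_gene", "estimate_variance_prior", "moderate_variances",
    "bh_adjust", "run_contrast", "run_de", "select_regulated",
    "consolidate_and_venn",
]


def fit_gene(values) -> tuple[float, float, int] | None:
    """One-sample fit: (lfc, residual variance, residual df) or ``None``
    if fewer than two replicates are available (untestable)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return None
    return float(x.mean()), float(x.var(ddof=1)), int(x.size - 1)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iterations)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray
                            ) -> tuple[float, float]:
    """Method-of-moments prior (d0, s0^2) from log gene-wise variances.

    Gene variances are modelled as scaled chi-square draws around a
    common prior variance with d0 prior degrees of freedom; matching the
    mean and variance of log(s^2) (via digamma/trigamma corrections)
    yields the estimates. A degenerate spread (all variances equal)
    gives an infinite prior df, i.e. a pooled-variance fall-back.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    if int(ok.sum()) < 10:
        raise ValueError("need >= 10 testable genes with positive variance "
                         "to estimate the variance prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    if z.var() < 1e-12:
        # literally identical gene variances: pool them directly
        logger.warning("degenerate variance distribution (all equal); "
                       "falling back to the pooled variance")
        pooled = float(np.average(s2[ok], weights=df[ok]))
        return np.inf, pooled
    surplus = evar - np.mean(special.polygamma(1, df[ok] / 2.0))
    if surplus <= 0:
        # spread consistent with pure sampling noise around one variance
        logger.warning("no excess variance heterogeneity; using an "
                       "infinite prior df (complete pooling)")
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(surplus)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0sq


def moderate_variances(
    lfc: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray,
    n: np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Posterior variances, moderated t statistics and p-values.

    posterior variance = (d0*s0^2 + d*s^2) / (d0 + d); moderated
    t = lfc / sqrt(posterior variance / n); two-sided p on d0 + d
    degrees of freedom. ``prior_df`` forces d0 (0 recovers the ordinary
    t statistic, inf makes every posterior variance equal s0^2).
    """
    lfc = np.asarray(lfc, float)
    s2 = np.asarray(s2, float)
    df = np.asarray(df, float)
    n = np.asarray(n, float)
    if prior_df is None:
        d0, s0sq = estimate_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        _, s0sq = estimate_variance_prior(s2, df) if d0 != 0 else (0.0, 0.0)
    if np.isinf(d0):
        post = np.full_like(s2, s0sq)
        total_df = np.full_like(df, np.inf)
    else:
        post = (d0 * s0sq + df * s2) / (d0 + df)
        total_df = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(post / n)
    p = np.where(np.isinf(total_df),
                 2.0 * stats.norm.sf(np.abs(t)),
                 2.0 * stats.t.sf(np.abs(t), np.maximum(total_df, 1e-9)))
    p = np.minimum(p, 1.0)
    return pd.DataFrame({"posterior_variance": post, "moderated_t": t,
                         "p_value": p, "prior_df": d0,
                         "prior_variance": s0sq})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_contrast(
    values: pd.DataFrame,
    strain: str,
    time_h: int,
    thresholds: AnalysisThresholds,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """DE results for one strain x time contrast.

    ``values``: genes x replicates log2 ratios (NaN = missing). Genes
    with fewer than two replicate values are untestable and excluded
    from this contrast only.
    """
    arr = values.to_numpy(dtype=float)
    n_obs = (~np.isnan(arr)).sum(axis=1)
    testable = n_obs >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lfc = np.nanmean(np.where(np.isnan(arr), np.nan, arr), axis=1)
        s2 = np.nanvar(arr, axis=1, ddof=1)
    sub = pd.DataFrame({
        "gene_id": values.index[testable],
        "strain": strain,
        "time_h": time_h,
        "lfc": lfc[testable],
        "residual_variance": s2[testable],
        "residual_df": n_obs[testable] - 1,
        "n_replicates": n_obs[testable],
    })
    mod = moderate_variances(sub["lfc"], sub["residual_variance"],
                             sub["residual_df"], sub["n_replicates"],
                             prior_df=prior_df)
    sub = pd.concat([sub.reset_index(drop=True), mod], axis=1)
    sub["fdr"] = bh_adjust(sub["p_value"])
    sub["regulated"] = (sub["fdr"] <= thresholds.fdr_cutoff) \
        & (sub["lfc"].abs() > thresholds.lfc_cutoff)
    sub["direction"] = np.where(
        ~sub["regulated"], "none", np.where(sub["lfc"] > 0, "up", "down"))
    return sub


def run_de(
    ratio_table: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """All contrasts of a replicate-level ratio table (wide columns
    ``strain_timeh_rK``)."""
    thresholds = thresholds or AnalysisThresholds()
    groups: dict[tuple[str, int], list[str]] = {}
    for col in ratio_table.columns:
        strain, t, _ = split_replicate_column(col)
        groups.setdefault((strain, t), []).append(col)
    results = []
    for (strain, t), cols in sorted(groups.items()):
        results.append(run_contrast(ratio_table[cols], strain, t,
                                    thresholds, prior_df=prior_df))
    return pd.concat(results, ignore_index=True)


def select_regulated(de: pd.DataFrame) -> pd.DataFrame:
    """Up/down counts per strain x time (bar-chart shape)."""
    reg = de[de["regulated"]]
    counts = (reg.groupby(["strain", "time_h", "direction"])
              .size().unstack(fill_value=0))
    for col in ("up", "down"):
        if col not in counts:
            counts[col] = 0
    return counts[["up", "down"]].reset_index()


def consolidate_and_venn(de: pd.DataFrame) -> dict:
    """Per-strain regulated gene sets (regulated at >= 1 time point),
    their specific/shared partition and the union size."""
    strains = sorted(de["strain"].unique())
    per_strain = {
        s: set(de.loc[(de["strain"] == s) & de["regulated"], "gene_id"])
        for s in strains
    }
    union = set().union(*per_strain.values()) if per_strain else set()
    out = {"per_strain": per_strain, "total": len(union), "union": union}
    if len(strains) == 2:
        a, b = strains
        out["venn"] = {
            f"specific_{a}": len(per_strain[a] - per_strain[b]),
            f"specific_{b}": len(per_strain[b] - per_strain[a]),
            "shared": len(per_strain[a] & per_strain[b]),
            "total": len(union),
        }
    return out
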