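"""RPKM-based comparison of time-0 basal expression between strains.

Gene-level counts per strain are converted to reads per kilobase of
exon per million mapped reads; log2 RPKM ratios (hyper producer over
moderate producer) identify genes with different basal levels via the
dual filter |log2 ratio| >= 4 and average reads > 100; results are
broken down per consensus cluster (higher / lower / equal basal level).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from lactokin.config import AnalysisThresholds

__all__ = [
    "compute_rpkm", "basal_compare", "cluster_distribution",
    "apply_reported_filter",
]

PSEUDOCOUNT = 0.5  # read-equivalent guarding against zero counts


def compute_rpkm(counts: pd.DataFrame,
                 totals: dict[str, float] | None = None) -> pd.DataFrame:
    """Attach rpkm = reads x 1e9 / (exon_length x total mapped reads).

    ``totals`` maps strain to the total mapped reads; by default the
    column sums of the table itself.
    """
    df = counts.copy()
    if totals is None:
        totals = df.groupby("strain")["reads"].sum().to_dict()
    for strain, total in totals.items():
        if total <= 0:
            raise ValueError(f"total mapped reads for {strain} must be > 0")
    if (df["exon_length_bp"] <= 0).any():
        raise ValueError("exon lengths must be > 0")
    t = df["strain"].map(totals)
    df["rpkm"] = df["reads"] * 1e9 / (df["exon_length_bp"] * t)
    return df


def basal_compare(
    counts: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
    strain_num: str = "RUTC30",
    strain_den: str = "NG14",
) -> pd.DataFrame:
    """Per-gene log2 RPKM ratio between strains with the dual filter.

    For genes with a zero count in either strain, a pseudo-count of
    half a read is added to both strains' counts before the RPKM
    computation so the ratio stays finite; fully observed genes are
    left untouched. The flag uses the absolute log ratio and the mean
    of the two strains' raw read counts. Genes absent from one strain
    count as 0.
    """
    thresholds = thresholds or AnalysisThresholds()
    totals = counts.groupby("strain")["reads"].sum().to_dict()
    wide_reads = (counts.pivot(index="gene_id", columns="strain",
                               values="reads")
                  .reindex(columns=[strain_num, strain_den]).fillna(0.0))
    lengths = (counts.groupby("gene_id")["exon_length_bp"].first()
               .reindex(wide_reads.index))
    any_zero = (wide_reads[strain_num] == 0) | (wide_reads[strain_den] == 0)
    rpkm = {}
    for strain in (strain_num, strain_den):
        adjusted = wide_reads[strain] + PSEUDOCOUNT * any_zero
        rpkm[strain] = adjusted * 1e9 / (lengths * totals[strain])
    out = pd.DataFrame({
        "gene_id": wide_reads.index,
        "log2_ratio": np.log2(rpkm[strain_num] / rpkm[strain_den]),
        "average_reads": wide_reads[[strain_num, strain_den]].mean(axis=1),
    }).reset_index(drop=True)
    out["flagged"] = (out["log2_ratio"].abs() >= thresholds.basal_logratio_min) \
        & (out["average_reads"] > thresholds.basal_reads_min)
    return out


def cluster_distribution(
    basal: pd.DataFrame,
    cluster_of: dict[str, int | str],
) -> pd.DataFrame:
    """Per-cluster counts and percentages of genes with a higher, lower
    or equal basal level in the numerator strain."""
    df = basal.copy()
    df["cluster"] = df["gene_id"].map(
        lambda g: cluster_of.get(g, "Not clustered"))
    df["status"] = np.where(
        ~df["flagged"], "equal",
        np.where(df["log2_ratio"] > 0, "higher", "lower"))
    counts = (df.groupby(["cluster", "status"]).size()
              .unstack(fill_value=0))
    for col in ("higher", "lower", "equal"):
        if col not in counts:
            counts[col] = 0
    counts = counts[["higher", "lower", "equal"]]
    counts["n_genes"] = counts.sum(axis=1)
    for col in ("higher", "lower", "equal"):
        counts[f"pct_{col}"] = 100.0 * counts[col] / counts["n_genes"]
    return counts.reset_index()


def apply_reported_filter(
    table: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
    ratio_col: str = "log2_ratio_rutc30_vs_ng14",
    reads_col: str = "average_reads",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-apply the dual filter to an already-summarized comparison
    table (log2 ratio + average reads columns).

    Returns (retained rows, discrepancy rows); a discrepancy is a
    listed row that violates the stated filter and must be reported,
    not silently kept.
    """
    thresholds = thresholds or AnalysisThresholds()
    ok = (table[ratio_col].abs() >= thresholds.basal_logratio_min) \
        & (table[reads_col] > thresholds.basal_reads_min)
    return table[ok].copy(), table[~ok].copy()
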