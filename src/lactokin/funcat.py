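"""Per-cluster functional-category tabulation (FunCat).

Main categories are those with strictly more than ten genes in the
analyzed set; the per-cluster table reports counts, row percentages
(rounded to the nearest integer) and an emphasis flag on the cluster
holding the category's maximum when it leads the runner-up by at least
two genes. Genes outside any main category are pooled under "Other
categories"; unclassified and unknown genes get their own rows.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from lactokin.config import AnalysisThresholds

logger = logging.getLogger(__name__)

__all__ = ["main_categories", "primary_category", "cluster_category_table"]


def primary_category(entries: pd.DataFrame) -> pd.DataFrame:
    """One curated category per gene: genes with several annotations are
    counted once, ties resolved by lowest category id (logged)."""
    dup = entries[entries["status"] == "classified"].groupby("gene_id").size()
    multi = dup[dup > 1]
    if len(multi):
        logger.info("%d genes with multiple categories resolved to the "
                    "lowest category id", len(multi))
    ordered = entries.sort_values(["gene_id", "category_id"])
    return ordered.drop_duplicates(subset="gene_id", keep="first")


def main_categories(
    entries: pd.DataFrame, min_genes: int = 10
) -> list[str]:
    """Category ids with strictly more than ``min_genes`` genes."""
    classified = primary_category(entries)
    classified = classified[classified["status"] == "classified"]
    counts = classified.groupby("category_id").size()
    return sorted(counts[counts > min_genes].index)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cluster_category_table(
    entries: pd.DataFrame,
    cluster_of: dict[str, int],
    thresholds: AnalysisThresholds | None = None,
) -> pd.DataFrame:
    """Counts, row percentages and emphasis per category x cluster.

    Only clustered genes are tabulated; a clustered gene with no entry
    is counted under "Unknown" with a warning. The emphasis column
    names the cluster holding the row maximum when it exceeds the
    runner-up by the configured margin; column totals across all rows
    (main + other + unclassified + unknown) equal the cluster sizes.
    """
    thresholds = thresholds or AnalysisThresholds()
    entries = primary_category(entries)
    entry_of = entries.set_index("gene_id")
    clusters = sorted(set(cluster_of.values()), key=str)
    genes = sorted(cluster_of)

    missing = [g for g in genes if g not in entry_of.index]
    if missing:
        logger.warning("%d clustered genes without a functional entry "
                       "counted as unknown", len(missing))

    analyzed = entries[entries["gene_id"].isin(cluster_of)]
    main = main_categories(analyzed, thresholds.funcat_main_min)
    names = (analyzed.drop_duplicates("category_id")
             .set_index("category_id")["category_name"].to_dict())

    def row_label(gid: str) -> str:
        if gid not in entry_of.index:
            return "Unknown"
        rec = entry_of.loc[gid]
        if rec["status"] == "unclassified":
            return "Unclassified"
        if rec["status"] == "unknown":
            return "Unknown"
        cat = rec["category_id"]
        return cat if cat in main else "Other categories"

    tab = pd.DataFrame(0, index=main + ["Other categories", "Unclassified",
                                        "Unknown"],
                       columns=clusters)
    for gid in genes:
        tab.loc[row_label(gid), cluster_of[gid]] += 1

    rows = []
    for cat in tab.index:
        counts = tab.loc[cat]
        total = int(counts.sum())
        ordered = counts.sort_values(ascending=False)
        emphasis = ""
        if total > 0 and (len(ordered) == 1
                          or ordered.iloc[0] - ordered.iloc[1]
                          >= thresholds.funcat_bold_margin):
            if ordered.iloc[0] > 0:
                emphasis = str(ordered.index[0])
        row = {"category_id": cat,
               "category_name": names.get(cat, cat),
               "total": total, "emphasis_cluster": emphasis}
        for cl in clusters:
            cnt = int(counts[cl])
            pct = _round_half_away(100.0 * cnt / total) if total else 0
            row[f"cluster_{cl}"] = cnt
            row[f"cluster_{cl}_pct"] = pct
        rows.append(row)
    table = pd.DataFrame(rows)
    # per-cluster totals row
    totals = {"category_id": "Total", "category_name": "",
              "total": int(tab.to_numpy().sum()), "emphasis_cluster": ""}
    for cl in clusters:
        totals[f"cluster_{cl}"] = int(tab[cl].sum())
        totals[f"cluster_{cl}_pct"] = ""
    return pd.concat([table, pd.DataFrame([totals])], ignore_index=True)
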