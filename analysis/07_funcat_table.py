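#!/usr/bin/env python
"""Per-cluster functional-category table with main-category and
emphasis rules (categories with > 10 genes; bold at a >= 2-gene lead).
"""

import argparse
from pathlib import Path

import pandas as pd

from lactokin.funcat import cluster_category_table

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

entries = pd.read_csv(args.outdir / "inputs" / "funcat.tsv", sep="\t",
                      keep_default_na=False)
clusters = pd.read_csv(args.outdir / "clusters.tsv", sep="\t")
cluster_of = {g: c for g, c in zip(clusters["gene_id"], clusters["cluster"])
              if c != 0}
table = cluster_category_table(entries, cluster_of)
table.to_csv(args.outdir / "funcat_table.tsv", sep="\t", index=False)
main_rows = table[~table["category_id"].isin(
    ["Other categories", "Unclassified", "Unknown", "Total"])]
print(f"{len(main_rows)} main categories over {len(cluster_of)} clustered "
      f"genes -> {args.outdir/'funcat_table.tsv'}")
print(table[["category_id", "category_name", "total",
             "emphasis_cluster"]].to_string(index=False))
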