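"""Published summary tables and dataset-level counts used as inputs.

These are the printed results of the original strain comparison:
dataset-level gene counts, the 23-row basal-expression comparison table
and the 19-row mutation-impact inventory. They serve as inputs for the
worked-number reproductions (percentage arithmetic, filter re-application
and contingency tabulation); nothing here is computed by this package.

The two TSVs were transcribed from the printed tables; a few read
counts carry a one-digit transcription ambiguity that cannot affect any
computed quantity (only the >100-reads rule consumes them, and the one
row near the boundary, the GAL80 regulator at 90 reads, is stated in
prose).
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

__all__ = ["COUNTS", "basal_comparison_table", "mutation_impact_table"]

# printed dataset-level counts (strain comparison over 4 time points)
COUNTS = {
    "de_genes_total": 568,          # DE vs time 0, both strains consolidated
    "clustered_genes": 532,         # genes sorted into the 9 final clusters
    "n_clusters": 9,
    "up_cluster_genes": 256,        # genes in the up-regulated clusters
    "down_cluster_genes": 276,      # genes in the down-regulated clusters
    "basal_different_genes": 23,    # DE genes with different basal level
    "ng14_specific": 319,
    "rutc30_specific": 62,
    "q_bradford_ng14": 1.2,         # mg/g_cell/h, 4-30 h window
    "q_bradford_rutc30": 3.98,
}


def _read(name: str) -> pd.DataFrame:
    text = resources.files("lactokin.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t")


def basal_comparison_table() -> pd.DataFrame:
    """The 23 genes reported with different basal expression (log2 RPKM
    ratio hyper/moderate producer and average reads)."""
    return _read("reported_basal_comparisons.tsv")


def mutation_impact_table() -> pd.DataFrame:
    """The mutation-impact inventory: 5 records from the producer
    lineage itself (4 specific to the hyper producer) and 14 from other
    cellulase-improved lineages."""
    return _read("reported_mutation_impacts.tsv")
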