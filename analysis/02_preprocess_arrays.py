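#!/usr/bin/env python
"""Probe-level two-channel data to transcript log2 ratios.

Per hybridization: M/A computation, global lowess normalization (no
background subtraction), background thresholding from the "not found"
features, detectability flagging; then orientation-corrected probe
averaging per transcript. Writes results/ratio_table.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from lactokin.microarray import preprocess_probe_table

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

probes = pd.read_csv(args.outdir / "inputs" / "probes.tsv", sep="\t",
                     dtype={"gene_id": str}, keep_default_na=False)
table = preprocess_probe_table(probes)
table.to_csv(args.outdir / "ratio_table.tsv", sep="\t",
             float_format="%.6g", na_rep="NA")
print(f"{table.shape[0]} transcripts x {table.shape[1]} hybridizations, "
      f"{int(table.isna().sum().sum())} discarded (missing) entries "
      f"-> {args.outdir/'ratio_table.tsv'}")
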