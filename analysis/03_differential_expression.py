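#!/usr/bin/env python
"""Moderated-t selection of regulated genes per strain and time point.

Selection at FDR <= 5% with |log2FC| > 1 within each contrast; writes
per-gene results, the up/down counts per condition and the
strain-specific/shared breakdown.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from lactokin import de as de_mod

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

ratio = pd.read_csv(args.outdir / "ratio_table.tsv", sep="\t", index_col=0,
                    na_values="NA")
de = de_mod.run_de(ratio)
de.to_csv(args.outdir / "de_results.tsv", sep="\t", index=False,
          float_format="%.6g")
counts = de_mod.select_regulated(de)
venn = de_mod.consolidate_and_venn(de)
summary = {"per_contrast": counts.to_dict(orient="records"),
           "venn": venn.get("venn", {}), "total": venn["total"]}
(args.outdir / "de_summary.json").write_text(
    json.dumps(summary, indent=1, sort_keys=True))
print(f"{venn['total']} regulated genes in >= 1 contrast; "
      f"venn {venn.get('venn')}")
print(counts.to_string(index=False))
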