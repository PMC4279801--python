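"""End-to-end orchestration with provenance.

``run_pipeline`` executes preprocess -> differential expression ->
consensus clustering -> basal comparison -> mutation windows -> FunCat
table -> bioprocess metrics over a directory of inputs (or a freshly
generated synthetic dataset), skipping any stage whose inputs are
absent, and writes a manifest with the configuration snapshot, input
digests, per-stage record counts and — in synthetic mode — the
recovery diagnostics against the known ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from lactokin import cluster as cl
from lactokin import de as de_mod
from lactokin import funcat as fc
from lactokin import mutation as mut
from lactokin import rnaseq as rs
from lactokin.bioprocess import bradford_to_lowry_range, carbon_balance, \
    specific_productivity
from lactokin.config import AnalysisThresholds, save_config
from lactokin.microarray import preprocess_probe_table
from lactokin.synthetic import GroundTruth, SyntheticConfig, generate_all

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "recovery_ari", "regulated_truth_sets"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def recovery_ari(labels: pd.Series, true_cluster: dict[str, int]) -> float:
    """Adjusted Rand index of the final assignment against the true
    archetypes, over all matrix genes; unclustered genes count as
    singleton labels (an honest penalty)."""
    genes = [g for g in labels.index if g in true_cluster]
    if not genes:
        return float("nan")
    truth = [true_cluster[g] for g in genes]
    pred = []
    for i, g in enumerate(genes):
        lab = int(labels.loc[g])
        pred.append(lab if lab != cl.UNCLUSTERED else -(i + 1))
    return float(adjusted_rand_score(truth, pred))


def regulated_truth_sets(truth: GroundTruth) -> dict[str, set[str]]:
    """Per-condition truly regulated gene sets from the ground truth."""
    out: dict[str, set[str]] = {}
    for gene, conds in truth.true_regulated.items():
        for cond, direction in conds.items():
            if direction != "none":
                out.setdefault(cond, set()).add(gene)
    return out


def run_pipeline(
    thresholds: AnalysisThresholds | None = None,
    inputs: str | Path | None = None,
    outdir: str | Path = "results/pipeline",
    seed: int = 0,
    synthetic_config: SyntheticConfig | None = None,
) -> dict:
    """Run every stage whose inputs exist; return the manifest.

    ``inputs=None`` requests synthetic mode: a dataset is generated
    under ``outdir/inputs`` with ``synthetic_config`` (defaults, with
    the given seed) and the pipeline consumes it.
    """
    thresholds = thresholds or AnalysisThresholds()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {},
                      "config": dataclasses.asdict(thresholds)}

    truth: GroundTruth | None = None
    if inputs is None:
        syn = synthetic_config or SyntheticConfig(seed=seed)
        indir = outdir / "inputs"
        truth = generate_all(syn, indir)
        manifest["synthetic_config"] = dataclasses.asdict(syn)
    else:
        indir = Path(inputs)
        gt = indir / "ground_truth.json"
        if gt.exists():
            truth = GroundTruth.from_json(gt)
    manifest["inputs"] = {p.name: _digest(p)
                          for p in sorted(indir.glob("*")) if p.is_file()}
    save_config(thresholds, outdir / "config.yaml")

    ratio_table = None
    probes_path = indir / "probes.tsv"
    if probes_path.exists():
        probes = pd.read_csv(probes_path, sep="\t",
                             dtype={"gene_id": str}, keep_default_na=False)
        ratio_table = preprocess_probe_table(probes, thresholds)
        ratio_table.to_csv(outdir / "ratio_table.tsv", sep="\t",
                           float_format="%.6g", na_rep="NA")
        manifest["stages"]["preprocess"] = {
            "genes": int(ratio_table.shape[0]),
            "missing_cells": int(ratio_table.isna().sum().sum()),
        }
    else:
        manifest["stages"]["preprocess"] = "skipped (no probes.tsv)"

    de = None
    venn = None
    if ratio_table is not None:
        de = de_mod.run_de(ratio_table, thresholds)
        de.to_csv(outdir / "de_results.tsv", sep="\t", index=False,
                  float_format="%.6g")
        counts = de_mod.select_regulated(de)
        venn = de_mod.consolidate_and_venn(de)
        summary = {
            "per_contrast": counts.to_dict(orient="records"),
            "venn": venn.get("venn", {}),
            "total": venn["total"],
        }
        (outdir / "de_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        manifest["stages"]["differential_expression"] = summary
    else:
        manifest["stages"]["differential_expression"] = "skipped"

    assignment = None
    if de is not None and venn and venn["total"] >= 20:
        matrix = cl.build_expression_matrix(ratio_table, venn["union"])
        assignment = cl.run_clustering(matrix, thresholds, seed=seed)
        pd.DataFrame({
            "gene_id": assignment.labels.index,
            "cluster": assignment.labels.to_numpy(),
            "direction": [assignment.directions.get(int(l), "")
                          for l in assignment.labels.to_numpy()],
        }).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        assignment.mean_profiles.to_csv(outdir / "cluster_profiles.tsv",
                                        sep="\t", float_format="%.6g")
        stage = {
            "matrix_genes": int(assignment.labels.size),
            "assigned": int((assignment.labels != cl.UNCLUSTERED).sum()),
            "unclustered": len(assignment.unclustered),
            "n_clusters": len(assignment.clusters),
            "directions": {str(k): v
                           for k, v in sorted(assignment.directions.items())},
        }
        if truth is not None:
            stage["recovery_ari"] = recovery_ari(assignment.labels,
                                                 truth.true_cluster)
        manifest["stages"]["clustering"] = stage
    else:
        manifest["stages"]["clustering"] = "skipped"

    counts_path = indir / "counts.tsv"
    if counts_path.exists():
        counts_df = pd.read_csv(counts_path, sep="\t")
        basal = rs.basal_compare(counts_df, thresholds)
        basal.to_csv(outdir / "basal_comparison.tsv", sep="\t", index=False,
                     float_format="%.6g")
        stage = {"genes": int(len(basal)),
                 "flagged": int(basal["flagged"].sum())}
        if assignment is not None:
            dist = rs.cluster_distribution(basal, assignment.cluster_of())
            dist.to_csv(outdir / "basal_by_cluster.tsv", sep="\t",
                        index=False, float_format="%.4g")
            stage["clusters"] = int(len(dist))
        manifest["stages"]["rnaseq_basal"] = stage
    else:
        manifest["stages"]["rnaseq_basal"] = "skipped (no counts.tsv)"

    gff_path = indir / "gene_models.gff3"
    mut_path = indir / "mutations.tsv"
    if gff_path.exists() and mut_path.exists() and venn is not None:
        genes = mut.load_gene_models_gff3(gff_path)
        mutations = mut.read_mutations_tsv(mut_path)
        impacts, report = mut.window_assign(mutations, genes,
                                            thresholds.mutation_window)
        cluster_of = assignment.cluster_of() if assignment else {}
        records = mut.intersect_regulated(impacts, venn["union"], cluster_of)
        records.to_csv(outdir / "mutation_impacts.tsv", sep="\t", index=False)
        table = mut.tabulate_by_cluster_and_lineage(records)
        table.to_csv(outdir / "mutation_table.tsv", sep="\t")
        manifest["stages"]["mutation_integration"] = {
            **report, "de_gene_records": int(len(records))}
    else:
        manifest["stages"]["mutation_integration"] = "skipped"

    funcat_path = indir / "funcat.tsv"
    if funcat_path.exists() and assignment is not None:
        entries = pd.read_csv(funcat_path, sep="\t", keep_default_na=False)
        table = fc.cluster_category_table(entries, assignment.cluster_of(),
                                          thresholds)
        table.to_csv(outdir / "funcat_table.tsv", sep="\t", index=False)
        manifest["stages"]["funcat"] = {"rows": int(len(table))}
    else:
        manifest["stages"]["funcat"] = "skipped"

    cult_path = indir / "cultivation.tsv"
    if cult_path.exists():
        series = pd.read_csv(cult_path, sep="\t")
        t1, t2 = 4.0, 30.0
        q = specific_productivity(series, t1, t2)
        low, high = bradford_to_lowry_range(
            q, thresholds.bradford_factor_low, thresholds.bradford_factor_high)
        ratio, ok = carbon_balance(series, thresholds.carbon_balance_min)
        metrics = {"q_bradford_mg_g_h": q, "q_lowry_low": low,
                   "q_lowry_high": high, "carbon_balance": ratio,
                   "carbon_balance_pass": bool(ok),
                   "interval_h": [t1, t2]}
        (outdir / "metrics.json").write_text(
            json.dumps(metrics, indent=1, sort_keys=True))
        manifest["stages"]["bioprocess_metrics"] = metrics
    else:
        manifest["stages"]["bioprocess_metrics"] = "skipped"

    manifest["outputs"] = {p.name: _digest(p)
                           for p in sorted(outdir.glob("*"))
                           if p.is_file() and p.name != "manifest.json"}
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=float))
    return manifest
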