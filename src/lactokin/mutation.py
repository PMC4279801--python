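"""Mutation-to-gene window mapping and Table-3-style tabulation.

A gene is considered affected by a mutation when the mutation falls
within the window delimited by 800 bp before the start codon and 800 bp
after the stop codon. Assigned mutations are classified by the region
hit (promoter / exon / intron / terminator, strand-aware), intersected
with the differentially expressed gene sets and tabulated by cluster
and mutagenesis lineage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

import gffutils

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel", "Mutation", "MutationImpact",
    "load_gene_models_gff3", "write_gene_models_gff3",
    "window_assign", "intersect_regulated", "tabulate_by_cluster_and_lineage",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene on a contig, 1-based inclusive coordinates.

    ``start``/``end`` span the coding sequence (start codon to stop
    codon), which is what the 800-bp proximity window is anchored on.
    """
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str                       # "+" or "-"
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for lo, hi in self.exons:
            if not (self.start <= lo <= hi <= self.end):
                raise ValueError(f"{self.gene_id}: exon outside gene span")

    @property
    def start_codon(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end

    @property
    def stop_codon(self) -> int:
        """Genomic position of the last base of the stop codon."""
        return self.end if self.strand == "+" else self.start

    @property
    def exon_length(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.exons)


@dataclass(frozen=True)
class Mutation:
    contig: str
    position: int
    type: str                        # SNV, InDel or SV
    lineages: frozenset[str] = frozenset()
    mutation_id: str = ""
    end: int | None = None           # SVs may span an interval

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("mutation position must be >= 1")

    @property
    def span(self) -> tuple[int, int]:
        return self.position, self.end if self.end is not None else self.position


@dataclass(frozen=True)
class MutationImpact:
    mutation: Mutation
    gene_id: str
    region: str                      # promoter / exon / intron / terminator
    de_status: bool | None = None
    cluster: int | str | None = None


def write_gene_models_gff3(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([
            g.contig, "lactokin", "gene", str(g.start), str(g.end), ".",
            g.strand, ".", f"ID={g.gene_id}",
        ]))
        for i, (lo, hi) in enumerate(g.exons, 1):
            lines.append("\t".join([
                g.contig, "lactokin", "exon", str(lo), str(hi), ".",
                g.strand, ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id}",
            ]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene + exon features from a GFF3 file via gffutils."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(sorted(
            (e.start, e.end) for e in db.children(feat, featuretype="exon")
        ))
        if not exons:
            exons = ((feat.start, feat.end),)
        genes.append(GeneModel(
            gene_id=feat.id, contig=feat.seqid, start=feat.start,
            end=feat.end, strand=feat.strand, exons=exons,
        ))
    return genes


def read_mutations_tsv(path: str | Path) -> list[Mutation]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    muts = []
    for i, row in df.iterrows():
        lineages = frozenset(str(row["lineages"]).split(",")) \
            if "lineages" in df.columns and pd.notna(row["lineages"]) else frozenset()
        end = int(row["end"]) if "end" in df.columns and pd.notna(row.get("end")) else None
        muts.append(Mutation(
            contig=str(row["contig"]), position=int(row["position"]),
            type=str(row["type"]), lineages=lineages,
            mutation_id=str(row.get("mutation_id", f"m{i:05d}")), end=end,
        ))
    return muts


def classify_region(gene: GeneModel, position: int) -> str:
    """Region label for a position already known to be inside the window."""
    if position < gene.start:
        return "promoter" if gene.strand == "+" else "terminator"
    if position > gene.end:
        return "terminator" if gene.strand == "+" else "promoter"
    for lo, hi in gene.exons:
        if lo <= position <= hi:
            return "exon"
    return "intron"


def window_assign(
    mutations: list[Mutation],
    genes: list[GeneModel],
    window: int = 800,
) -> tuple[list[MutationImpact], dict]:
    """Assign each mutation to every gene whose window it falls in.

    The window is [start - window, end + window] on the gene's coding
    span, boundaries inclusive ("within the window"); it is symmetric,
    so assignment is strand-independent while the promoter/terminator
    labelling is strand-aware. SV records spanning an interval count as
    affecting a gene if any covered base is inside the window.

    Returns the impact list plus a run report with the number of
    mutations skipped for unknown contigs.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree intervals are half-open, hence end + window + 1
        trees.setdefault(g.contig, IntervalTree()).addi(
            g.start - window, g.end + window + 1, g)
    known_contigs = set(trees)
    impacts: list[MutationImpact] = []
    skipped = 0
    for m in mutations:
        if m.contig not in known_contigs:
            logger.warning("mutation %s on unknown contig %s skipped",
                           m.mutation_id, m.contig)
            skipped += 1
            continue
        lo, hi = m.span
        for iv in sorted(trees[m.contig].overlap(lo, hi + 1),
                         key=lambda iv: iv.data.gene_id):
            gene = iv.data
            # classify from the first affected base inside the window
            pos = max(lo, gene.start - window)
            impacts.append(MutationImpact(
                mutation=m, gene_id=gene.gene_id,
                region=classify_region(gene, pos)))
    report = {"n_mutations": len(mutations), "n_assigned": len(impacts),
              "n_skipped_unknown_contig": skipped}
    return impacts, report


def intersect_regulated(
    impacts: list[MutationImpact],
    regulated_union: set[str],
    cluster_of: dict[str, int | str] | None = None,
) -> pd.DataFrame:
    """Keep impacts on differentially expressed genes; attach clusters.

    ``cluster_of`` maps gene id to final consensus cluster; genes absent
    from it are reported as "Not clustered".
    """
    cluster_of = cluster_of or {}
    rows = []
    for imp in impacts:
        if imp.gene_id not in regulated_union:
            continue
        rows.append({
            "mutation_id": imp.mutation.mutation_id,
            "gene_id": imp.gene_id,
            "region": imp.region,
            "type": imp.mutation.type,
            "lineage_group": " & ".join(sorted(imp.mutation.lineages)) or "unknown",
            "cluster": cluster_of.get(imp.gene_id, "Not clustered"),
        })
    return pd.DataFrame(
        rows, columns=["mutation_id", "gene_id", "region", "type",
                       "lineage_group", "cluster"])


def tabulate_by_cluster_and_lineage(records: pd.DataFrame) -> pd.DataFrame:
    """Contingency table cluster x lineage group with margins."""
    if records.empty:
        return pd.DataFrame({"All": {"All": 0}})
    table = pd.crosstab(
        records["cluster"].astype(str), records["lineage_group"],
        margins=True, margins_name="All")
    return table
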