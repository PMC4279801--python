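"""Consensus K-means clustering of regulated-gene expression profiles.

The regulated genes' strain x time log2-ratio matrix is filtered for
missing values (> 30% missing removed, remaining gaps treated as 0 —
the no-change value — for distances only), K is chosen from an
average-linkage Euclidean dendrogram, several independent random-start
K-means runs are aggregated through a gene x gene co-occurrence matrix,
and the final clusters are the average-linkage cut of (1 - C) at the
co-occurrence threshold; loosely attached genes are left unclustered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import cdist, pdist, squareform

from lactokin.config import AnalysisThresholds

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment", "TieError", "build_expression_matrix",
    "filter_missing", "choose_k", "kmeans_run", "cooccurrence_matrix",
    "consensus_aggregate", "classify_direction", "run_clustering",
]

UNCLUSTERED = 0  # label for genes left out of every final cluster


class TieError(ValueError):
    """A cluster's mean profile has an exactly zero extremum."""


@dataclass
class ClusterAssignment:
    """Final consensus clusters.

    ``labels`` maps every matrix gene to a cluster id (1..k) or
    ``UNCLUSTERED``; ``mean_profiles`` holds each cluster's mean
    expression profile; ``directions`` its up/down call.
    """
    labels: pd.Series
    mean_profiles: pd.DataFrame = field(default_factory=pd.DataFrame)
    directions: dict[int, str] = field(default_factory=dict)

    @property
    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for gene, lab in self.labels.items():
            if lab != UNCLUSTERED:
                out.setdefault(int(lab), []).append(gene)
        return out

    @property
    def unclustered(self) -> list[str]:
        return list(self.labels.index[self.labels == UNCLUSTERED])

    def cluster_of(self) -> dict[str, int]:
        return {g: int(l) for g, l in self.labels.items() if l != UNCLUSTERED}


def build_expression_matrix(
    ratio_table: pd.DataFrame, regulated: set[str]
) -> pd.DataFrame:
    """Genes x 8 conditions matrix for the regulated union: replicate
    columns ``strain_timeh_rK`` are averaged per condition (NaN where
    every replicate is missing)."""
    cols: dict[str, list[str]] = {}
    for col in ratio_table.columns:
        cond = col.rsplit("_", 1)[0]
        cols.setdefault(cond, []).append(col)
    sub = ratio_table.loc[sorted(regulated & set(ratio_table.index))]
    return pd.DataFrame({cond: sub[cs].mean(axis=1)
                         for cond, cs in cols.items()})


def filter_missing(
    matrix: pd.DataFrame, max_fraction: float = 0.30
) -> pd.DataFrame:
    """Drop genes with strictly more than ``max_fraction`` missing."""
    frac = matrix.isna().mean(axis=1)
    out = matrix.loc[frac <= max_fraction]
    if out.empty:
        raise ValueError("no genes left after the missing-value filter")
    return out


def _imputed(matrix: pd.DataFrame) -> np.ndarray:
    # 0 = no change on the log2-ratio scale; for distances only
    return matrix.fillna(0.0).to_numpy(dtype=float)


def choose_k(matrix: pd.DataFrame, k_min: int = 2, k_max: int = 15) -> int:
    """K from the average-linkage dendrogram: the cut with the largest
    relative merge-height gap, scanned over [k_min, k_max]."""
    x = _imputed(matrix)
    n = x.shape[0]
    if n < 20:
        raise ValueError("need >= 20 genes to choose K")
    heights = average(pdist(x))[:, 2]          # ascending merge heights
    k_max = min(k_max, n - 1)
    best_k, best_gap = k_min, -np.inf
    if heights[-1] <= 0:
        logger.warning("degenerate structure (all profiles identical); "
                       "using K = %d", k_min)
        return k_min
    for k in range(k_min, k_max + 1):
        upper = heights[n - k]                 # first merge the cut removes
        lower = heights[n - k - 1] if n - k - 1 >= 0 else 0.0
        gap = upper / max(lower, 1e-12)
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def kmeans_run(matrix: pd.DataFrame, k: int, seed: int,
               max_iter: int = 300, n_restarts: int = 50) -> np.ndarray:
    """One K-means run: Lloyd iterations with Euclidean distance.

    Centroids start at k distinct random observations; iteration stops
    when the assignment stabilizes; a cluster that empties is re-seeded
    from the point farthest from its centroid. A single random start on
    well-separated groups regularly converges with two groups sharing a
    centroid, so each run performs ``n_restarts`` seeded random starts
    and keeps the assignment with the lowest within-cluster sum of
    squares — the standard guard against initialization collapse.
    """
    x = _imputed(matrix)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"K = {k} exceeds the {n} genes available")
    if k < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    best_labels, best_sse = None, np.inf
    for _ in range(max(1, n_restarts)):
        centroids = x[rng.choice(n, size=k, replace=False)].copy()
        labels = np.full(n, -1)
        for _ in range(max_iter):
            d = cdist(x, centroids)
            new_labels = d.argmin(axis=1)
            for j in range(k):
                members = new_labels == j
                if members.any():
                    centroids[j] = x[members].mean(axis=0)
                else:
                    far = d[np.arange(n), new_labels].argmax()
                    centroids[j] = x[far]
                    new_labels[far] = j
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        sse = float(((x - centroids[labels]) ** 2).sum())
        if sse < best_sse:
            best_labels, best_sse = labels, sse
    return best_labels


def cooccurrence_matrix(label_runs: list[np.ndarray]) -> np.ndarray:
    """Symmetric gene x gene fraction of runs co-clustering each pair."""
    if len(label_runs) < 2:
        raise ValueError("need >= 2 runs to aggregate")
    n = len(label_runs[0])
    if any(len(l) != n for l in label_runs):
        raise ValueError("runs cover inconsistent gene sets")
    c = np.zeros((n, n))
    for labels in label_runs:
        labels = np.asarray(labels)
        c += (labels[:, None] == labels[None, :]).astype(float)
    return c / len(label_runs)


def consensus_aggregate(
    label_runs: list[np.ndarray],
    genes: list[str],
    threshold: float = 0.60,
) -> pd.Series:
    """Final clusters from the run ensemble.

    Average-linkage hierarchical clustering of the distance (1 - C) is
    cut at height (1 - threshold), so genes merge while their average
    co-occurrence stays >= the threshold. Singleton groups, and genes
    whose mean co-occurrence with the rest of their group falls below
    the threshold, are marked unclustered (iterated to stability).
    Cluster ids are relabelled 1..k by decreasing size (ties by first
    gene) — invariant to run order.
    """
    c = cooccurrence_matrix(label_runs)
    n = len(genes)
    raw = fcluster(average(squareform(1.0 - c, checks=False)),
                   t=1.0 - threshold, criterion="distance")
    labels = np.asarray(raw, dtype=int)
    active = np.ones(n, dtype=bool)
    changed = True
    while changed:
        changed = False
        for grp in np.unique(labels[active]):
            members = np.flatnonzero(active & (labels == grp))
            if len(members) == 1:
                active[members] = False
                changed = True
                continue
            sub = c[np.ix_(members, members)]
            mean_co = (sub.sum(axis=1) - 1.0) / (len(members) - 1.0)
            weak = members[mean_co < threshold]
            if len(weak):
                active[weak] = False
                changed = True
    final = np.full(n, UNCLUSTERED, dtype=int)
    groups = {}
    for i in np.flatnonzero(active):
        groups.setdefault(labels[i], []).append(i)
    ordered = sorted(groups.values(), key=lambda idx: (-len(idx), idx[0]))
    for new_id, idx in enumerate(ordered, start=1):
        final[idx] = new_id
    return pd.Series(final, index=list(genes), name="cluster")


def classify_direction(mean_profile: np.ndarray | pd.Series) -> str:
    """Sign of the mean-profile value of largest magnitude."""
    v = np.asarray(mean_profile, dtype=float)
    extremum = v[np.nanargmax(np.abs(v))]
    if extremum == 0:
        raise TieError("mean profile extremum is exactly zero")
    return "up" if extremum > 0 else "down"


def run_clustering(
    matrix: pd.DataFrame,
    thresholds: AnalysisThresholds | None = None,
    seed: int = 0,
    k: int | None = None,
) -> ClusterAssignment:
    """Filter, choose K, run the K-means ensemble and aggregate.

    The per-run seeds derive deterministically from the master seed.
    """
    thresholds = thresholds or AnalysisThresholds()
    matrix = filter_missing(matrix, thresholds.missing_fraction_max)
    if k is None:
        k = choose_k(matrix)
    run_seeds = np.random.SeedSequence(seed).generate_state(
        thresholds.kmeans_runs)
    runs = [kmeans_run(matrix, k, int(s) % (2**31))
            for s in run_seeds]
    labels = consensus_aggregate(runs, list(matrix.index),
                                 thresholds.cooccurrence_threshold)
    profiles = {}
    directions = {}
    for cid, members in sorted(
            ClusterAssignment(labels).clusters.items()):
        prof = matrix.loc[members].mean(axis=0, skipna=True)
        profiles[cid] = prof
        directions[cid] = classify_direction(prof.to_numpy())
    mean_profiles = pd.DataFrame(profiles).T
    mean_profiles.index.name = "cluster"
    return ClusterAssignment(labels=labels, mean_profiles=mean_profiles,
                             directions=directions)
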