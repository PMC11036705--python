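"""Tumor cell-state lineage scoring and per-cluster state assignment.

A cell's lineage score for a state is the mean expression over that state's
signature genes divided by the mean expression over all genes in the cell,
so a uniformly expressing cell scores exactly 1 for every state.  Each
cluster is assigned the state with the highest mean score across its cells;
ties break by the declared state order and are flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["SignatureSet", "LineageScoreTable", "lineage_score", "assign_cluster_states", "baseline_clusters"]


@dataclass
class SignatureSet:
    """Ordered cell states, each with a gene list."""

    states: tuple[str, ...]
    genes_per_state: Mapping[str, Sequence[str]]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "SignatureSet":
        return cls(tuple(mapping.keys()), {k: list(v) for k, v in mapping.items()})

    def intersect(self, gene_ids: Sequence[str]) -> "SignatureSet":
        """Restrict every list to the genes present in a matrix; empty overlap is an error."""
        present = set(gene_ids)
        out = {}
        for state in self.states:
            genes = [g for g in self.genes_per_state[state] if g in present]
            if not genes:
                raise ValueError(f"state {state!r} has no signature genes in the expression matrix")
            if len(genes) < len(self.genes_per_state[state]):
                logger.warning("state %s: %d/%d signature genes present",
                               state, len(genes), len(self.genes_per_state[state]))
            out[state] = genes
        return SignatureSet(self.states, out)


@dataclass
class LineageScoreTable:
    scores: pd.DataFrame                      # cells x states
    cluster_labels: pd.Series | None = None   # cell -> cluster
    cluster_mean_scores: pd.DataFrame | None = None  # clusters x states
    cluster_state: pd.Series | None = None    # cluster -> assigned state
    ties: list = field(default_factory=list)  # clusters where the argmax was tied


def lineage_score(expr: NormalizedMatrix, signatures: SignatureSet) -> LineageScoreTable:
    """Per-cell state scores: mean over signature genes / mean over all genes."""
    sigs = signatures.intersect(expr.gene_ids)
    gene_index = pd.Index(expr.gene_ids)
    all_mean = expr.values.mean(axis=0)
    zero = all_mean == 0
    if zero.any():
        logger.warning("%d cells have zero mean expression; their scores are 0", int(zero.sum()))
    denom = np.where(zero, 1.0, all_mean)
    cols = {}
    for state in sigs.states:
        rows = gene_index.get_indexer(sigs.genes_per_state[state])
        state_mean = expr.values[rows].mean(axis=0)
        cols[state] = np.where(zero, 0.0, state_mean / denom)
    scores = pd.DataFrame(cols, index=expr.unit_ids)[list(sigs.states)]
    return LineageScoreTable(scores=scores)


def assign_cluster_states(
    table: LineageScoreTable,
    cluster_labels: pd.Series | Mapping[str, object],
) -> LineageScoreTable:
    """Mean score per cluster; each cluster gets the argmax state (declared-order ties)."""
    labels = pd.Series(cluster_labels)
    missing = set(table.scores.index) - set(labels.index)
    if missing:
        raise ValueError(f"cells without a cluster label: {sorted(missing)[:5]}")
    labels = labels.loc[table.scores.index]
    if labels.isna().any():
        raise ValueError("cells with missing cluster labels")
    means = table.scores.groupby(labels).mean()
    if means.empty:
        raise ValueError("empty cluster encountered")
    states = list(table.scores.columns)
    assigned, ties = {}, []
    for cluster, row in means.iterrows():
        best = row.max()
        winners = [s for s in states if row[s] == best]
        if len(winners) > 1:
            ties.append(cluster)
            logger.warning("cluster %s: tied lineage scores %s; keeping %s",
                           cluster, winners, winners[0])
        assigned[cluster] = winners[0]
    return LineageScoreTable(
        scores=table.scores,
        cluster_labels=labels,
        cluster_mean_scores=means,
        cluster_state=pd.Series(assigned, name="state"),
        ties=ties,
    )


def baseline_clusters(expr: NormalizedMatrix, k: int = 10, n_pcs: int = 20, seed: int = 0) -> pd.Series:
    """Convenience k-means-on-PCs clustering for when no labels are supplied."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = expr.values.T  # cells x genes
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(x - x.mean(axis=0))
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pcs)
    return pd.Series(km.labels_.astype(str), index=expr.unit_ids, name="cluster")
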