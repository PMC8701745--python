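"""The three-stage gene-selection cascade run inside each LOO fold.

Stage 1 clusters gene expression profiles with a deterministic k-means
and drops whole clusters whose centroid never reaches a detectable level
(most genes sit in a few large, homogeneous, low-expression clusters).
Stage 2 keeps genes whose between-group difference of mean log2
expression is at least ``delta_min`` (a log2-scale threshold: 0.5 is
deliberately permissive, a raw-ratio reading would mean a 2-fold
change).  Stage 3 operates across folds: each gene's frequency of
appearance among the per-fold post-fold-change sets is computed, and the
final panel keeps genes appearing in at least a fraction ``f_min`` of
folds — low-frequency genes would seed non-general decision trees.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import ParameterError, InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneClustering:
    """k-means clustering of genes (points) over samples (dimensions)."""

    k: int
    gene_ids: tuple[str, ...]
    labels: np.ndarray  # cluster id per gene
    centroids: np.ndarray  # k x n_samples
    inertia: float
    n_iter: int

    @property
    def assignment(self) -> dict[str, int]:
        return {g: int(c) for g, c in zip(self.gene_ids, self.labels)}

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in zip(self.gene_ids, self.labels) if c == cluster]


@dataclass
class SelectionTrace:
    """Per-fold record of the genes surviving each cascade stage.

    ``retained_final`` is filled in after cross-fold aggregation (the
    frequency filter is defined at the aggregate level) and satisfies
    retained_final ⊆ retained_after_fc_filter ⊆ retained_after_cluster_filter.
    """

    fold_id: str
    retained_after_cluster_filter: tuple[str, ...]
    retained_after_fc_filter: tuple[str, ...]
    retained_final: tuple[str, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "retained_after_cluster_filter": list(self.retained_after_cluster_filter),
            "retained_after_fc_filter": list(self.retained_after_fc_filter),
            "retained_final": list(self.retained_final or ()),
        }


@dataclass(frozen=True)
class FrequencyTable:
    """Fraction of folds in which each gene survived the cascade."""

    counts: Mapping[str, int]
    n_folds: int

    def frequency(self, gene: str) -> float:
        return self.counts.get(gene, 0) / self.n_folds

    @property
    def frequencies(self) -> dict[str, float]:
        return {g: c / self.n_folds for g, c in self.counts.items()}

    def genes(self) -> list[str]:
        return list(self.counts)


@dataclass(frozen=True)
class PanelResult:
    """The aggregate frequency-filtered gene panel."""

    panel: tuple[str, ...]
    frequencies: Mapping[str, float]
    f_min: float

    def __iter__(self):
        return iter(self.panel)

    def __len__(self) -> int:
        return len(self.panel)


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


def _squared_distances(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    p2 = (points**2).sum(axis=1)[:, None]
    c2 = (centroids**2).sum(axis=1)[None, :]
    d2 = p2 + c2 - 2.0 * points @ centroids.T
    np.maximum(d2, 0.0, out=d2)
    return d2


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centroids = np.empty((k, points.shape[1]))
    first = int(rng.integers(n))
    centroids[0] = points[first]
    d2 = _squared_distances(points, centroids[:1]).ravel()
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))  # all points coincide with a centroid
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[i] = points[idx]
        d2 = np.minimum(d2, _squared_distances(points, centroids[i : i + 1]).ravel())
    return centroids


def cluster_genes(
    expr: ExpressionMatrix, k: int, seed: int, max_iter: int = 300
) -> GeneClustering:
    """Deterministic Lloyd's k-means with k-means++-style seeding.

    Genes are the points, samples the dimensions.  Equidistant points go
    to the lower cluster index; an emptied cluster is reseeded with the
    point farthest from its current centroid.  Iteration stops at an
    assignment fixed point (or ``max_iter``), after which centroids are
    exact member means.
    """
    points = expr.values.astype(float)
    n = points.shape[0]
    if k > n:
        raise ParameterError(f"k={k} exceeds the number of genes ({n})")
    if k <= 0:
        raise ParameterError("k must be positive")
    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(points, k, rng)
    labels = np.full(n, -1)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = _squared_distances(points, centroids)
        new_labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        # reseed empty clusters with the farthest point from its centroid
        counts = np.bincount(new_labels, minlength=k)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            current = d2[np.arange(n), new_labels]
            order = np.argsort(-current, kind="stable")
            pos = 0
            for cluster in empty:
                while counts[new_labels[order[pos]]] <= 1:
                    pos += 1
                donor = order[pos]
                counts[new_labels[donor]] -= 1
                new_labels[donor] = cluster
                counts[cluster] += 1
                pos += 1
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for cluster in range(k):
            mask = labels == cluster
            centroids[cluster] = points[mask].mean(axis=0)
    # final exact centroids and inertia for the converged assignment
    for cluster in range(k):
        mask = labels == cluster
        centroids[cluster] = points[mask].mean(axis=0)
    inertia = float(
        _squared_distances(points, centroids)[np.arange(n), labels].sum()
    )
    return GeneClustering(
        k=k,
        gene_ids=tuple(expr.gene_ids),
        labels=labels.copy(),
        centroids=centroids.copy(),
        inertia=inertia,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# cascade filters
# ---------------------------------------------------------------------------


def detectability_filter(clustering: GeneClustering, tau_detect: float) -> list[str]:
    """Keep all genes of clusters whose centroid max coordinate >= tau_detect."""
    if tau_detect < 0:
        raise ParameterError("tau_detect must be >= 0 on the log2(CPM+1) scale")
    keep_cluster = clustering.centroids.max(axis=1) >= tau_detect
    return [
        g
        for g, c in zip(clustering.gene_ids, clustering.labels)
        if keep_cluster[c]
    ]


def fold_change_filter(
    expr: ExpressionMatrix,
    groups: pd.Series,
    genes: Iterable[str],
    delta_min: float = 0.5,
    group_test: str = "DCM",
    group_ref: str = "HS",
) -> list[str]:
    """Keep genes with |mean log2(test) - mean log2(ref)| >= delta_min."""
    genes = list(genes)
    unknown = [g for g in genes if g not in expr.frame.index]
    if unknown:
        raise InputError(f"genes not in expression matrix: {unknown[:5]}")
    groups = groups.astype(str).loc[expr.sample_ids]
    test_cols = [s for s in expr.sample_ids if groups[s] == group_test]
    ref_cols = [s for s in expr.sample_ids if groups[s] == group_ref]
    sub = expr.frame.loc[genes]
    delta = sub[test_cols].mean(axis=1) - sub[ref_cols].mean(axis=1)
    return [g for g in genes if abs(delta[g]) >= delta_min]


def aggregate_frequencies(traces: Sequence[SelectionTrace]) -> FrequencyTable:
    """Appearance fraction of each gene among the post-FC-filter sets."""
    if not traces:
        raise InputError("need at least one selection trace")
    counts: dict[str, int] = {}
    for trace in traces:
        for gene in trace.retained_after_fc_filter:
            counts[gene] = counts.get(gene, 0) + 1
    return FrequencyTable(counts=counts, n_folds=len(traces))


def frequency_filter(freqs: FrequencyTable, f_min: float = 0.75) -> PanelResult:
    """Panel = genes with frequency >= f_min, sorted by (freq desc, id asc)."""
    if not 0 <= f_min <= 1:
        raise ParameterError(f"f_min must be in [0, 1], got {f_min}")
    frequencies = freqs.frequencies
    panel = sorted(
        (g for g, f in frequencies.items() if f >= f_min),
        key=lambda g: (-frequencies[g], g),
    )
    if not panel:
        logger.warning("frequency filter produced an empty panel (f_min=%s)", f_min)
    return PanelResult(panel=tuple(panel), frequencies=frequencies, f_min=f_min)


def select_genes(
    expr: ExpressionMatrix,
    groups: pd.Series,
    fold_id: str,
    k: int,
    tau_detect: float,
    delta_min: float,
    seed: int,
) -> SelectionTrace:
    """Run cluster + detectability + fold-change stages on one training set."""
    clustering = cluster_genes(expr, k=k, seed=seed)
    after_cluster = detectability_filter(clustering, tau_detect)
    after_fc = fold_change_filter(expr, groups, after_cluster, delta_min)
    return SelectionTrace(
        fold_id=fold_id,
        retained_after_cluster_filter=tuple(after_cluster),
        retained_after_fc_filter=tuple(after_fc),
    )
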