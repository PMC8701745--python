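"""Gene-set over-representation and PPI subnetwork extraction.

Over-representation is the one-sided hypergeometric upper tail: with a
universe of N genes, a set of K members (after intersection with the
universe) and a query of n genes overlapping the set in k, the p-value
is P(X >= k) computed by direct summation of the hypergeometric pmf.
Sets are flat (GMT semantics); no ontology hierarchy is modeled.

Subnetwork extraction keeps edges of a scored interaction table whose
score is strictly above a threshold, whose channel is in the requested
subset, and which touch at least one seed gene (first-neighbor mode).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSetCollection
from .diffexp import bh_adjust
from .errors import InputError, ParameterError
from .io import CHANNELS


@dataclass(frozen=True)
class EnrichmentResult:
    """Per gene set: overlap k, set size K, query n, universe N, p, BH fdr."""

    frame: pd.DataFrame  # columns: set, k, K, n, N, p, fdr

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def top(self, m: int = 20) -> pd.DataFrame:
        return self.frame.sort_values(["p", "set"], kind="stable").head(m)


def hypergeom_ora(
    query: Iterable[str], universe: Iterable[str], sets: GeneSetCollection
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of each gene set against the query."""
    universe_set = set(universe)
    query_set = set(query)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise InputError(f"query genes outside the universe: {offenders[:10]}")
    n_universe = len(universe_set)
    n_query = len(query_set)

    rows = []
    for gene_set in sets:
        members = set(gene_set.genes) & universe_set
        big_k = len(members)
        k = len(members & query_set)
        if big_k == 0:
            p = 1.0
        else:
            upper = min(big_k, n_query)
            ks = np.arange(k, upper + 1)
            p = float(stats.hypergeom.pmf(ks, n_universe, big_k, n_query).sum())
            p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            {"set": gene_set.name, "k": k, "K": big_k, "n": n_query, "N": n_universe, "p": p}
        )
    frame = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    frame["fdr"] = bh_adjust(frame["p"].to_numpy()) if len(frame) else []
    return EnrichmentResult(frame)


@dataclass(frozen=True)
class Subnetwork:
    """Score- and channel-filtered first-neighbor subnetwork of the seeds."""

    edges: pd.DataFrame
    nodes: tuple[str, ...]
    seeds: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.edges)


def subnetwork(
    edges: pd.DataFrame,
    seeds: Iterable[str],
    score_min: float = 0.7,
    channels: Iterable[str] = ("physical",),
) -> Subnetwork:
    """Edges with score > score_min (strict), channel in ``channels``, and
    at least one endpoint among the seed genes."""
    if not 0 <= score_min <= 1:
        raise ParameterError(f"score_min must be in [0, 1], got {score_min}")
    channels = tuple(channels)
    unknown = [c for c in channels if c not in CHANNELS]
    if unknown:
        raise ParameterError(f"unknown channel(s) {unknown}; expected subset of {CHANNELS}")
    seed_set = set(seeds)
    if seed_set:
        keep = (
            (edges["score"] > score_min)
            & edges["channel"].isin(channels)
            & (edges["protein_a"].isin(seed_set) | edges["protein_b"].isin(seed_set))
        )
        kept = edges[keep].reset_index(drop=True)
    else:
        kept = edges.iloc[0:0].reset_index(drop=True)
    nodes = sorted(set(kept["protein_a"]) | set(kept["protein_b"]))
    return Subnetwork(edges=kept, nodes=tuple(nodes), seeds=tuple(sorted(seed_set)))
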