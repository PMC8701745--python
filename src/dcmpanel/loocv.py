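"""Leave-one-out orchestration of selection, tree training and scoring.

Each of the n folds holds out one sample and reruns the entire upstream
cascade — candidate-gene filtering, normalization, batch-offset
estimation, clustering, detectability and fold-change filtering — on the
training samples only, so nothing about the held-out sample leaks into
the selection or the tree thresholds.  The design is two-pass: after all
folds' selection traces are known, gene appearance frequencies are
aggregated, the frequency filter defines the final cross-fold panel, and
a second pass trains per-fold trees that use those aggregate frequencies
as the stable criterion's prior.  Both the stable and the standard trees
are kept so their censuses can be contrasted.

Per-fold sub-seeds are derived deterministically from the master seed,
so identical inputs and seed give byte-identical serialized results.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .containers import CountsMatrix, ExpressionMatrix, SampleMetadata
from .errors import InputError
from .preprocess import apply_batch_offsets, batch_offsets, cpm_log2, filter_low_expression
from .selection import (
    FrequencyTable,
    PanelResult,
    SelectionTrace,
    aggregate_frequencies,
    frequency_filter,
    select_genes,
)
from .tree import DecisionTree, Leaf, TreeCensus, census, fit_tree, predict, serialize_tree

logger = logging.getLogger(__name__)


@dataclass
class FoldOutcome:
    fold_id: str
    held_out: str
    truth: str
    trace: SelectionTrace | None = None
    tree_stable: DecisionTree | None = None
    tree_standard: DecisionTree | None = None
    prediction: str | None = None
    error: str | None = None

    @property
    def completed(self) -> bool:
        return self.error is None


@dataclass
class LoocvResult:
    """Everything the cross-validated run produced."""

    n_folds: int
    folds: list[FoldOutcome]
    frequency_table: FrequencyTable
    panel: PanelResult
    census_stable: TreeCensus
    census_standard: TreeCensus
    accuracy: float
    n_completed: int

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "n_completed": self.n_completed,
            "accuracy": self.accuracy,
            "panel": list(self.panel.panel),
            "panel_frequencies": {
                g: self.frequency_table.frequency(g) for g in sorted(self.frequency_table.counts)
            },
            "census_stable": self.census_stable.to_dict(),
            "census_standard": self.census_standard.to_dict(),
            "folds": [
                {
                    "fold_id": f.fold_id,
                    "held_out": f.held_out,
                    "truth": f.truth,
                    "prediction": f.prediction,
                    "error": f.error,
                    "trace": f.trace.to_dict() if f.trace else None,
                    "tree_stable": serialize_tree(f.tree_stable) if f.tree_stable else None,
                    "tree_standard": serialize_tree(f.tree_standard) if f.tree_standard else None,
                }
                for f in self.folds
            ],
        }


def _fold_seed(master_seed: int, fold_index: int) -> int:
    seq = np.random.SeedSequence([int(master_seed), int(fold_index)])
    return int(seq.generate_state(1)[0] % (2**31))


def _fold_expression(
    counts: CountsMatrix,
    metadata: SampleMetadata,
    train_samples: list[str],
    config: PipelineConfig,
) -> ExpressionMatrix:
    """Gene filter + normalization + batch offsets, fit on training only.

    Returns expression for *all* samples (normalization is per-sample;
    batch offsets are estimated on the training samples and then applied
    to every sample of that batch, held-out one included).
    """
    train_counts = counts.subset_samples(train_samples)
    filtered = filter_low_expression(
        train_counts, config.filter_min_count, config.filter_min_fraction
    )
    # CPM uses the full per-sample library (all genes), so a sample's
    # normalized values do not depend on which genes the fold retained
    expr_all = cpm_log2(counts, pseudocount=config.pseudocount).subset_genes(
        filtered.gene_ids
    )
    batches = metadata.batches
    if batches.nunique() > 1:
        offsets = batch_offsets(expr_all.subset_samples(train_samples), batches)
        expr_all = apply_batch_offsets(expr_all, offsets, batches)
    return expr_all


def _fallback_candidates(trace: SelectionTrace, expr: ExpressionMatrix) -> list[str]:
    """Candidate genes for tree fitting, falling back up the cascade."""
    for stage in (
        trace.retained_final,
        trace.retained_after_fc_filter,
        trace.retained_after_cluster_filter,
    ):
        if stage:
            return list(stage)
    return []


def _majority_tree(labels: pd.Series) -> DecisionTree:
    counts = labels.value_counts().to_dict()
    best = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == best)
    label = "DCM" if "DCM" in winners else winners[0]
    return DecisionTree(root=Leaf(label=label, support={str(k): int(v) for k, v in sorted(counts.items())}))


def run_loocv(
    counts: CountsMatrix, metadata: SampleMetadata, config: PipelineConfig | None = None
) -> LoocvResult:
    """One training run per sample, aggregate panel, census and accuracy."""
    config = config or PipelineConfig()
    metadata = metadata.aligned_to(counts.sample_ids)
    samples = counts.sample_ids
    groups = metadata.groups
    for level in ("DCM", "HS"):
        if (groups == level).sum() < 3:
            raise InputError(f"need >= 3 samples per class, got {(groups == level).sum()} {level!r}")

    folds: list[FoldOutcome] = []
    expressions: dict[str, ExpressionMatrix] = {}

    # pass 1: per-fold preprocessing + selection cascade
    for i, held_out in enumerate(samples):
        fold_id = f"fold_{i:02d}"
        outcome = FoldOutcome(fold_id=fold_id, held_out=held_out, truth=str(groups[held_out]))
        train = [s for s in samples if s != held_out]
        train_groups = groups.loc[train]
        if train_groups.nunique() < 2:
            outcome.error = "a class is absent from the training fold"
            logger.warning("%s skipped: %s", fold_id, outcome.error)
            folds.append(outcome)
            continue
        expr_all = _fold_expression(counts, metadata, train, config)
        expressions[fold_id] = expr_all
        expr_train = expr_all.subset_samples(train)
        outcome.trace = select_genes(
            expr_train,
            train_groups,
            fold_id=fold_id,
            k=min(config.selection_k, len(expr_train.gene_ids)),
            tau_detect=config.selection_tau_detect,
            delta_min=config.selection_delta_min,
            seed=_fold_seed(config.seed, i),
        )
        folds.append(outcome)

    completed = [f for f in folds if f.completed]
    if not completed:
        raise InputError("every fold failed; cannot aggregate")

    # aggregate: frequencies over post-FC sets, panel at aggregate level
    freq = aggregate_frequencies([f.trace for f in completed])
    panel = frequency_filter(freq, config.selection_f_min)
    panel_set = set(panel.panel)
    for f in completed:
        f.trace.retained_final = tuple(
            g for g in f.trace.retained_after_fc_filter if g in panel_set
        )

    # pass 2: per-fold trees (standard on the fold's post-FC set, stable on
    # the fold's slice of the aggregate panel with the frequency prior)
    for f in completed:
        expr_all = expressions[f.fold_id]
        train = [s for s in samples if s != f.held_out]
        expr_train = expr_all.subset_samples(train)
        train_labels = groups.loc[train]

        std_candidates = list(f.trace.retained_after_fc_filter)
        if std_candidates:
            f.tree_standard = fit_tree(
                expr_train,
                train_labels,
                std_candidates,
                criterion="standard",
                max_depth=config.tree_max_depth,
                min_leaf=config.tree_min_leaf,
            )
        else:
            f.tree_standard = _majority_tree(train_labels)

        stable_candidates = _fallback_candidates(f.trace, expr_train)
        if stable_candidates:
            f.tree_stable = fit_tree(
                expr_train,
                train_labels,
                stable_candidates,
                criterion="stable",
                stability_prior=freq,
                max_depth=config.tree_max_depth,
                min_leaf=config.tree_min_leaf,
            )
        else:
            f.tree_stable = _majority_tree(train_labels)

        chosen = f.tree_stable if config.tree_criterion == "stable" else f.tree_standard
        f.prediction = predict(chosen, expr_all.sample_vector(f.held_out))

    correct = sum(1 for f in completed if f.prediction == f.truth)
    acc = correct / len(completed)

    return LoocvResult(
        n_folds=len(samples),
        folds=folds,
        frequency_table=freq,
        panel=panel,
        census_stable=census([f.tree_stable for f in completed]),
        census_standard=census([f.tree_standard for f in completed]),
        accuracy=acc,
        n_completed=len(completed),
    )


def accuracy(result: LoocvResult) -> float:
    """Correct held-out predictions / completed folds."""
    if result.n_completed == 0:
        raise InputError("no completed folds")
    return result.accuracy
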