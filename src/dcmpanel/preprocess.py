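"""Normalization, candidate-gene filtering and batch-effect removal.

Normalization is log2(CPM + pseudocount); the default pseudocount of 1
keeps zero counts at exactly 0 and all values non-negative.  Batch
correction is a gene-wise location adjustment: each batch's values are
shifted so every batch mean equals the gene's global mean.  Group labels
are deliberately not used (the cohorts this targets have batch partially
confounded with group, and a group-aware correction would leak labels).
"""
from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import CountsMatrix, ExpressionMatrix
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


def filter_low_expression(
    counts: CountsMatrix, min_count: int = 10, min_fraction: float = 0.25
) -> CountsMatrix:
    """Keep genes with count >= min_count in >= ceil(min_fraction * n) samples."""
    if not 0 < min_fraction <= 1:
        raise ParameterError(f"min_fraction must be in (0, 1], got {min_fraction}")
    n_samples = len(counts.sample_ids)
    need = math.ceil(min_fraction * n_samples)
    keep = (counts.values >= min_count).sum(axis=1) >= need
    if not keep.any():
        logger.warning(
            "low-expression filter removed every gene (min_count=%s, min_fraction=%s)",
            min_count,
            min_fraction,
        )
    return CountsMatrix(counts.frame.loc[keep])


def cpm_log2(counts: CountsMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count / library_size * 1e6 + pseudocount), per sample."""
    values = counts.values.astype(float)
    libraries = values.sum(axis=0)
    zero = np.flatnonzero(libraries == 0)
    if zero.size:
        raise InputError(f"sample {counts.sample_ids[zero[0]]!r} has zero library size")
    cpm = values / libraries[None, :] * 1e6
    expr = np.log2(cpm + pseudocount)
    return ExpressionMatrix(
        pd.DataFrame(expr, index=counts.frame.index, columns=counts.frame.columns)
    )


def batch_offsets(
    expr: ExpressionMatrix, batches: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-gene additive offsets (global mean - batch mean), genes x batches.

    Fit on the samples present in ``expr``; apply with
    :func:`apply_batch_offsets` (possibly to other samples of the same
    batches, e.g. a held-out sample in cross-validation).
    """
    labels = _batch_labels(expr, batches)
    frame = expr.frame
    global_mean = frame.mean(axis=1)
    offsets = {}
    for batch in sorted(set(labels.values())):
        cols = [s for s in frame.columns if labels[s] == batch]
        offsets[batch] = global_mean - frame[cols].mean(axis=1)
    return pd.DataFrame(offsets, index=frame.index)


def apply_batch_offsets(
    expr: ExpressionMatrix,
    offsets: pd.DataFrame,
    batches: Mapping[str, str] | pd.Series,
) -> ExpressionMatrix:
    labels = _batch_labels(expr, batches)
    out = expr.frame.copy()
    for sample in out.columns:
        batch = labels[sample]
        if batch not in offsets.columns:
            raise InputError(f"no fitted offset for batch {batch!r}")
        out[sample] = out[sample] + offsets[batch].reindex(out.index).fillna(0.0)
    return ExpressionMatrix(out)


def batch_correct(
    expr: ExpressionMatrix, batches: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Center every batch to the per-gene global mean (location only).

    A pure location shift: within-batch rank order per gene is preserved,
    and single-batch input is returned unchanged.
    """
    offsets = batch_offsets(expr, batches)
    return apply_batch_offsets(expr, offsets, batches)


def _batch_labels(
    expr: ExpressionMatrix, batches: Mapping[str, str] | pd.Series
) -> dict[str, str]:
    if isinstance(batches, pd.Series):
        mapping = {str(k): str(v) for k, v in batches.items()}
    else:
        mapping = {str(k): str(v) for k, v in batches.items()}
    missing = [s for s in expr.sample_ids if s not in mapping]
    if missing:
        raise InputError(f"samples without a batch label: {missing}")
    return mapping
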