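"""Per-gene two-group differential expression with BH-FDR.

The test is a Welch two-sample t on log2(CPM + 1) expression: at the
cohort sizes this pipeline targets (about 11 per group) a location test
on the log scale is robust and adequate, and count-model GLMs are out of
scope.  log2FC is the difference of group means on the log2 scale
(DCM - HS).  Multiple testing uses the Benjamini-Hochberg step-up
procedure.

Zero-variance conventions (deterministic and test-visible): a gene with
identical values in both groups gets t = 0, p = 1; a gene with zero
variance in both groups but unequal means gets p = 0 with a warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import InputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DEResult:
    """Per-gene log2FC, Welch t, p, BH-FDR and direction (up/down/flat)."""

    frame: pd.DataFrame  # columns: log2fc, t, p, fdr, direction

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene")


def de_test(
    expr: ExpressionMatrix,
    groups: pd.Series,
    group_test: str = "DCM",
    group_ref: str = "HS",
) -> DEResult:
    """Welch t per gene; log2FC = mean(group_test) - mean(group_ref)."""
    groups = groups.astype(str)
    missing = [s for s in expr.sample_ids if s not in groups.index]
    if missing:
        raise InputError(f"samples without a group label: {missing}")
    groups = groups.loc[expr.sample_ids]
    test_cols = [s for s in expr.sample_ids if groups[s] == group_test]
    ref_cols = [s for s in expr.sample_ids if groups[s] == group_ref]
    if len(test_cols) < 2 or len(ref_cols) < 2:
        raise InputError(
            f"need >= 2 samples per group, got {len(test_cols)} {group_test!r} "
            f"and {len(ref_cols)} {group_ref!r}"
        )

    a = expr.frame[test_cols].to_numpy(dtype=float)
    b = expr.frame[ref_cols].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    log2fc = mean_a - mean_b
    se2 = var_a / na + var_b / nb

    t = np.zeros(len(log2fc))
    p = np.ones(len(log2fc))
    regular = se2 > 0
    if regular.any():
        t_reg = log2fc[regular] / np.sqrt(se2[regular])
        df = se2[regular] ** 2 / (
            (var_a[regular] / na) ** 2 / (na - 1) + (var_b[regular] / nb) ** 2 / (nb - 1)
        )
        t[regular] = t_reg
        p[regular] = 2.0 * stats.t.sf(np.abs(t_reg), df)
    degenerate = (~regular) & (log2fc != 0)
    if degenerate.any():
        t[degenerate] = np.sign(log2fc[degenerate]) * np.inf
        p[degenerate] = 0.0
        logger.warning(
            "%d gene(s) with zero variance in both groups but unequal means (p set to 0)",
            int(degenerate.sum()),
        )

    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "flat"))
    frame = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": bh_adjust(p),
            "direction": direction,
        },
        index=expr.frame.index,
    )
    return DEResult(frame)


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def filter_degs(result: DEResult, p_max: float = 0.01) -> list[str]:
    """Genes with p strictly below p_max, sorted by p ascending."""
    sub = result.frame[result.frame["p"] < p_max]
    sub = sub.sort_values("p", kind="stable")
    return [str(g) for g in sub.index]


@dataclass(frozen=True)
class TopDEGs:
    """Stringently filtered gene list with its up/down partition sizes."""

    genes: tuple[str, ...]
    n_up: int
    n_down: int

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def filter_top_degs(
    result: DEResult, fdr_max: float = 0.05, lfc_min: float = 1.0
) -> TopDEGs:
    """Genes with fdr < fdr_max and |log2FC| > lfc_min (both strict)."""
    frame = result.frame
    keep = (frame["fdr"] < fdr_max) & (frame["log2fc"].abs() > lfc_min)
    sub = frame[keep].sort_values("p", kind="stable")
    genes = tuple(str(g) for g in sub.index)
    n_up = int((sub["direction"] == "up").sum())
    n_down = int((sub["direction"] == "down").sum())
    return TopDEGs(genes, n_up, n_down)
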