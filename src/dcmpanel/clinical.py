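"""Spearman association between panel genes and clinical covariates.

Small-cohort correlation needs honest p-values: for n <= 8 pairs the
two-sided p is exact, obtained by enumerating all n! permutations of the
observed (mid)ranks; for larger n the usual t approximation
t = rho * sqrt(n-2) / sqrt(1 - rho^2) with n-2 degrees of freedom is
used.  Ties are handled with midranks, and the exact enumeration
permutes the observed midrank vector itself.

Significance follows the screening convention of the cohort study this
pipeline targets: |rho| > 0.5 (strict) and p <= 0.05 (inclusive — a pair
sitting exactly at p = 0.05 counts).  No multiple-testing correction is
applied to the pass flag, but a BH-adjusted column is emitted alongside
for transparency.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleMetadata
from .diffexp import bh_adjust
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

#: n at or below which the permutation p-value is exact
EXACT_N_MAX = 8

_PERMS: dict[int, np.ndarray] = {}


def _permutations(n: int) -> np.ndarray:
    if n not in _PERMS:
        _PERMS[n] = np.array(list(itertools.permutations(range(n))), dtype=np.int16)
    return _PERMS[n]


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value (exact for n <= 8).

    Returns (nan, nan) with a warning when either variable has zero rank
    variance (rho undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise InputError(f"need n >= 3 observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    ssx = float(rxc @ rxc)
    ssy = float(ryc @ ryc)
    if ssx == 0 or ssy == 0:
        logger.warning("zero rank variance: Spearman rho undefined")
        return (float("nan"), float("nan"))
    rho = float(rxc @ ryc / math.sqrt(ssx * ssy))

    if n <= EXACT_N_MAX:
        perms = _permutations(n)
        rho_all = (ryc[perms] @ rxc) / math.sqrt(ssx * ssy)
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return (rho, min(p, 1.0))


@dataclass(frozen=True)
class CorrelationResult:
    """Gene x covariate grid of rho, p, n_used, pass flag and BH column."""

    frame: pd.DataFrame  # columns: gene, covariate, rho, p, n_used, passed, fdr
    rho_min: float
    p_max: float

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _parse_stratum(stratum) -> tuple[str, str] | None:
    if stratum is None:
        return None
    if isinstance(stratum, str):
        if "=" not in stratum:
            raise ParameterError(f"stratum must look like 'COLUMN=value', got {stratum!r}")
        column, value = stratum.split("=", 1)
        return column.strip(), value.strip()
    column, value = stratum
    return str(column), str(value)


def correlate_panel(
    expr: ExpressionMatrix,
    panel: list[str],
    metadata: SampleMetadata,
    stratum=None,
    rho_min: float = 0.5,
    p_max: float = 0.05,
) -> CorrelationResult:
    """Spearman over the full panel x covariate grid, pairwise-complete.

    ``stratum`` optionally restricts samples by a metadata column, e.g.
    ``"NYHA=3"`` keeps only class-III patients before correlating.
    """
    unknown = [g for g in panel if g not in expr.frame.index]
    if unknown:
        raise InputError(f"panel genes not in expression matrix: {unknown[:5]}")
    meta = metadata.aligned_to(expr.sample_ids)
    samples = expr.sample_ids

    parsed = _parse_stratum(stratum)
    if parsed is not None:
        column, value = parsed
        if column not in meta.frame.columns:
            raise InputError(f"stratum column {column!r} not in metadata")
        mask = meta.frame[column].astype(str) == value
        samples = [s for s, m in zip(samples, mask) if m]
        if len(samples) < 3:
            raise InputError(
                f"stratum {column}={value} leaves only {len(samples)} samples (need >= 3)"
            )

    clinical = meta.frame.loc[samples, meta.clinical_columns]
    covariates = [
        c
        for c in clinical.columns
        if (parsed is None or c != parsed[0]) and pd.api.types.is_numeric_dtype(clinical[c])
    ]

    rows = []
    for gene in panel:
        gvals = expr.frame.loc[gene, samples].to_numpy(dtype=float)
        for cov in covariates:
            cvals = clinical[cov].to_numpy(dtype=float)
            complete = np.isfinite(gvals) & np.isfinite(cvals)
            n_used = int(complete.sum())
            if n_used < 3:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman(gvals[complete], cvals[complete])
            passed = bool(
                not math.isnan(rho) and abs(rho) > rho_min and p <= p_max
            )
            rows.append(
                {
                    "gene": gene,
                    "covariate": cov,
                    "rho": rho,
                    "p": p,
                    "n_used": n_used,
                    "passed": passed,
                }
            )
    frame = pd.DataFrame(rows, columns=["gene", "covariate", "rho", "p", "n_used", "passed"])
    valid = frame["p"].notna()
    fdr = np.full(len(frame), np.nan)
    if valid.any():
        fdr[valid.to_numpy()] = bh_adjust(frame.loc[valid, "p"].to_numpy())
    frame["fdr"] = fdr
    return CorrelationResult(frame=frame, rho_min=rho_min, p_max=p_max)


def significant_pairs(
    result: CorrelationResult, rho_min: float | None = None, p_max: float | None = None
) -> pd.DataFrame:
    """Pairs with |rho| > rho_min (strict) and p <= p_max, sorted by p."""
    rho_min = result.rho_min if rho_min is None else rho_min
    p_max = result.p_max if p_max is None else p_max
    frame = result.frame
    keep = frame["rho"].abs().gt(rho_min) & frame["p"].le(p_max)
    return (
        frame[keep]
        .sort_values(["p", "gene", "covariate"], kind="stable")
        .reset_index(drop=True)
    )
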