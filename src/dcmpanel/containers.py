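"""In-memory containers for the pipeline's tabular data.

All containers are thin, validated wrappers around a :class:`pandas.DataFrame`
so that downstream modules can rely on their invariants (unique identifiers,
non-negative integer counts, matching axes) without re-checking them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

GROUP_LEVELS = ("DCM", "HS")


def _check_unique(values: Iterable[str], what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise InputError(f"duplicate {what} id: {v!r}")
        seen.add(v)


@dataclass(frozen=True)
class CountsMatrix:
    """Raw gene x sample read counts (non-negative integers).

    ``frame`` is indexed by gene id with sample ids as columns; row and
    column order are meaningful and preserved by every operation.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "gene")
        _check_unique(self.frame.columns, "sample")
        values = self.frame.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise InputError("counts must be numeric")
            if np.any(values < 0):
                i, j = np.argwhere(values < 0)[0]
                raise InputError(
                    f"negative count at gene {self.frame.index[i]!r}, "
                    f"sample {self.frame.columns[j]!r}"
                )
            if not np.issubdtype(values.dtype, np.integer):
                frac = values != np.floor(values)
                if np.any(frac):
                    i, j = np.argwhere(frac)[0]
                    raise InputError(
                        f"non-integer count at gene {self.frame.index[i]!r}, "
                        f"sample {self.frame.columns[j]!r}"
                    )
                object.__setattr__(self, "frame", self.frame.astype(np.int64))

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def subset_genes(self, genes: Iterable[str]) -> "CountsMatrix":
        return CountsMatrix(self.frame.loc[list(genes)])

    def subset_samples(self, samples: Iterable[str]) -> "CountsMatrix":
        return CountsMatrix(self.frame[list(samples)])


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized log2(CPM + pseudocount) expression, genes x samples."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "gene")
        _check_unique(self.frame.columns, "sample")
        if self.frame.size and not np.issubdtype(self.frame.to_numpy().dtype, np.number):
            raise InputError("expression values must be numeric")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[list(genes)])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame[list(samples)])

    def sample_vector(self, sample: str) -> dict[str, float]:
        """Expression of one sample as a gene -> value mapping."""
        if sample not in self.frame.columns:
            raise InputError(f"unknown sample id: {sample!r}")
        return self.frame[sample].to_dict()


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations: disease group, batch, clinical covariates.

    ``frame`` is indexed by sample id.  A ``group`` column with levels
    DCM/HS is mandatory; ``batch`` is optional (a single batch is assumed
    when absent); any remaining columns are treated as clinical covariates
    and may contain missing values.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")
        if "group" not in self.frame.columns:
            raise InputError("metadata must contain a 'group' column")
        levels = set(self.frame["group"].dropna().astype(str))
        bad = levels - set(GROUP_LEVELS)
        if bad:
            raise InputError(
                f"unknown group labels {sorted(bad)}; expected {GROUP_LEVELS}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"].astype(str)

    @property
    def batches(self) -> pd.Series:
        if "batch" in self.frame.columns:
            return self.frame["batch"].astype(str)
        return pd.Series("batch0", index=self.frame.index, name="batch")

    @property
    def clinical_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("group", "batch")]

    def clinical(self) -> pd.DataFrame:
        return self.frame[self.clinical_columns]

    def aligned_to(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        """Reorder to match a counts/expression matrix; error on mismatch."""
        wanted = [str(s) for s in sample_ids]
        missing = [s for s in wanted if s not in self.frame.index]
        if missing:
            raise InputError(f"metadata missing samples: {missing}")
        return SampleMetadata(self.frame.loc[wanted])

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return self.aligned_to(sample_ids)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with GMT semantics (deduplicated, order-preserving)."""

    sets: Mapping[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)
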