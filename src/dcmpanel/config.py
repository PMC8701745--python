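"""Pipeline configuration: flat, namespaced keys with documented defaults.

Config files are YAML mappings whose keys use dotted namespaces
(``filter.min_count: 10``).  Unknown keys are rejected so that typos
cannot silently fall back to defaults.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError

#: dotted config key -> dataclass attribute
KEYMAP = {
    "filter.min_count": "filter_min_count",
    "filter.min_fraction": "filter_min_fraction",
    "normalization.pseudocount": "pseudocount",
    "batch.column": "batch_column",
    "selection.k": "selection_k",
    "selection.tau_detect": "selection_tau_detect",
    "selection.delta_min": "selection_delta_min",
    "selection.f_min": "selection_f_min",
    "tree.max_depth": "tree_max_depth",
    "tree.min_leaf": "tree_min_leaf",
    "tree.criterion": "tree_criterion",
    "diffexp.p_max": "diffexp_p_max",
    "diffexp.fdr_max": "diffexp_fdr_max",
    "diffexp.lfc_min": "diffexp_lfc_min",
    "clinical.rho_min": "clinical_rho_min",
    "clinical.p_max": "clinical_p_max",
    "clinical.stratum": "clinical_stratum",
    "network.score_min": "network_score_min",
    "network.channels": "network_channels",
    "seed": "seed",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable the pipeline exposes, with its default."""

    filter_min_count: int = 10
    filter_min_fraction: float = 0.25
    pseudocount: float = 1.0
    batch_column: str = "batch"
    selection_k: int = 100
    selection_tau_detect: float = 1.0
    selection_delta_min: float = 0.5
    selection_f_min: float = 0.75
    tree_max_depth: int = 3
    tree_min_leaf: int = 2
    tree_criterion: str = "stable"
    diffexp_p_max: float = 0.01
    diffexp_fdr_max: float = 0.05
    diffexp_lfc_min: float = 1.0
    clinical_rho_min: float = 0.5
    clinical_p_max: float = 0.05
    clinical_stratum: str | None = None
    network_score_min: float = 0.7
    network_channels: tuple[str, ...] = ("physical",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_criterion not in ("standard", "stable"):
            raise ParameterError(f"tree.criterion must be standard|stable, got {self.tree_criterion!r}")
        if isinstance(self.network_channels, (list, str)):
            channels = (
                tuple(c.strip() for c in self.network_channels.split(","))
                if isinstance(self.network_channels, str)
                else tuple(self.network_channels)
            )
            object.__setattr__(self, "network_channels", channels)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        unknown = [k for k in mapping if k not in KEYMAP]
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {KEYMAP[k]: v for k, v in mapping.items()}
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(Path(path)) as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: config must be a flat key-value mapping")
        return cls.from_mapping(raw)

    def to_mapping(self) -> dict:
        inverse = {v: k for k, v in KEYMAP.items()}
        out = {}
        for f in fields(self):
            value = getattr(self, f.name)
            if isinstance(value, tuple):
                value = list(value)
            out[inverse[f.name]] = value
        return out

    def replace(self, **kwargs) -> "PipelineConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)
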