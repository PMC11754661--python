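"""Run configuration shared by the CLI subcommands and the demo pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Unknown keys are rejected on construction from a mapping so that a
    typo in a config file fails loudly rather than silently using a
    default.
    """

    # LG4 scan
    density_threshold: float = 80.0  # GGG repeats per 1000 bp
    window: int = 1000
    step: int = 100
    min_lg4_length: int = 1000
    counting_mode: str = "tiling"
    # minimal motif finding
    loop_min: int = 1
    loop_max: int = 7
    # promoter windows
    promoter_window_bp: int = 5000
    strand_resolved: bool = True
    # enrichment
    gc_tolerance: float = 0.02
    n_control_sets: int = 3
    table_units: str = "slot"
    # alignment
    word_size: int = 15
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 100
    mask_min_len: int = 100
    # simulation
    n_reads: int = 300
    fragments_min: int = 3
    fragments_max: int = 8
    substitution_rate: float = 0.005
    neighborhood_bp: int = 25_000
    min_fragment_length: int = 150
    # global
    seed: int = 7

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)
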