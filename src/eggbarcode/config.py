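"""Run configuration.

All identity thresholds are fractions in (0, 1). Defaults encode the standard
barcoding practice this pipeline implements: species calls require more than
99% identity (strictly greater — 0.99 exactly fails), genus calls require
more than 95%, and lineages are delimited at 1% K2P divergence.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import InputError
from .records import MONTHS


@dataclass
class RunConfig:
    species_identity_threshold: float = 0.99
    genus_identity_floor: float = 0.95
    top_n_primary: int = 100
    top_n_fallback: int = 5
    bootstrap_reps: int = 1000
    lineage_cluster_threshold: float = 0.01
    rng_seed: int = 0
    exclusion_taxa: list[str] = field(default_factory=list)
    months: tuple[str, ...] = MONTHS
    # pairwise alignment scoring (gap of length L costs open + (L-1)*extend)
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    def __post_init__(self):
        if not (0.0 < self.genus_identity_floor <= self.species_identity_threshold < 1.0):
            raise InputError(
                "require 0 < genus_identity_floor <= species_identity_threshold < 1; "
                f"got floor={self.genus_identity_floor}, "
                f"threshold={self.species_identity_threshold}"
            )
        if self.top_n_primary < 1 or self.top_n_fallback < 1:
            raise InputError("top_n values must be >= 1")
        if self.bootstrap_reps < 0:
            raise InputError("bootstrap_reps must be >= 0")
        if self.lineage_cluster_threshold <= 0:
            raise InputError("lineage_cluster_threshold must be > 0")
        self.months = tuple(self.months)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["months"] = list(self.months)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InputError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
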