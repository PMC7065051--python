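"""Run configuration, provenance hashing, and seeded random streams.

One global seed is declared per run; each pipeline stage derives its own
independent stream deterministically from (seed, stage name), so stages
can be rerun in isolation and still reproduce the full-pipeline output
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

STAGES = ("flow", "pop", "ptm", "popgen", "hybrid", "connect")


def config_hash(config: dict[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named stage, derived from the global seed."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic stage-local integer seed below 2**31."""
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Per-stage parameter blocks plus the global seed and output directory.

    Stage blocks are plain mappings validated lazily by the stage
    constructors (e.g. ``PTMConfig(**cfg.ptm)``); :meth:`validate` runs all
    of them up front so a bad block fails before any stage executes.
    """

    seed: int = 0
    out_dir: str = "stepstone_out"
    flow: dict[str, Any] = field(default_factory=dict)
    pop: dict[str, Any] = field(default_factory=dict)
    ptm: dict[str, Any] = field(default_factory=dict)
    popgen: dict[str, Any] = field(default_factory=dict)
    hybrid: dict[str, Any] = field(default_factory=dict)
    connect: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            **{s: getattr(self, s if s != "pop" else "pop") for s in
               ("flow", "pop", "ptm", "popgen", "hybrid", "connect")},
        }

    @property
    def hash(self) -> str:
        return config_hash(self.as_dict())

    def provenance(self) -> list[str]:
        """Header lines stamped into every output file."""
        return [f"config_hash: {self.hash}", f"seed: {self.seed}"]

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)

    def validate(self) -> None:
        """Construct every stage config; raises before any stage runs."""
        # imported here to avoid circular imports at module load
        from .ptm import PTMConfig
        from .synthetic import FlowFieldSpec, PopSimSpec

        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.flow:
            FlowFieldSpec(**self.flow)
        if self.pop:
            PopSimSpec.from_mapping(self.pop)
        if self.ptm:
            PTMConfig(**{k: v for k, v in self.ptm.items() if k != "sites"})
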