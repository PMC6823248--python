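"""Pipeline configuration: input paths, thresholds, and simulation settings."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .core import ValidationError
from .gsva import ES_MAX_ABS, ES_SIGNED_SUM
from .simulate import CellModule, SimulationConfig


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic sub-seed for stage ``stream`` of a run seeded with ``seed``."""
    return int(np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0]
               % (2**31))


@dataclass
class PipelineConfig:
    """Everything a run needs; unset paths disable the stages that need them."""

    outdir: str = "immunosig_out"
    # inputs (filled in by the simulate stage when simulate=True)
    counts: str = ""
    design: str = ""
    gmt: str = ""
    registry_celltype: str = ""
    registry_functional: str = ""
    pathways: str = ""
    human_z: dict[str, str] = field(default_factory=dict)  # tissue -> Z-profile TSV
    counts_scale: str = "raw_counts"
    reference_group: str = ""
    # thresholds
    de_fdr: float = 0.1          # mouse-style contrast
    human_de_fdr: float = 0.05   # human-style contrasts in the compare stage
    z_cut: float = 2.0
    overlap_p: float = 0.05
    chi_p: float = 0.05
    go_p: float = 0.01
    min_tissues: int = 2
    # scoring
    tau: float = 1.0
    es_convention: str = ES_SIGNED_SUM
    # simulation
    simulate: bool = False
    n_human_tissues: int = 3
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0

    def validate(self) -> None:
        for name in ("de_fdr", "human_de_fdr", "overlap_p", "chi_p", "go_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1], got {v}")
        if self.z_cut <= 0:
            raise ValidationError(f"z_cut must be > 0, got {self.z_cut}")
        if self.min_tissues < 1:
            raise ValidationError("min_tissues must be >= 1")
        if self.es_convention not in (ES_SIGNED_SUM, ES_MAX_ABS):
            raise ValidationError(f"unknown es_convention {self.es_convention!r}")
        if self.counts_scale not in ("raw_counts", "log2"):
            raise ValidationError(f"unknown counts_scale {self.counts_scale!r}")
        if self.tau < 0:
            raise ValidationError("tau must be >= 0")
        if self.n_human_tissues < 1:
            raise ValidationError("n_human_tissues must be >= 1")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["modules"] = [dataclasses.asdict(m) for m in self.sim.modules]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("sim", {})
        if isinstance(sim, dict):
            sim = dict(sim)
            modules = sim.pop("modules", None)
            if modules is not None:
                sim["modules"] = tuple(CellModule(**m) for m in modules)
            sim = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(sim=sim, **data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
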