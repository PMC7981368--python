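"""Run configuration: a serializable record of every knob of a pipeline run.

The configuration is embedded (with its hash) in every output file a run
produces, so that any report can be traced back to the exact settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    pdb: str = ""
    segments: str | None = None
    chemistry_overrides: str | None = None
    # structure preparation
    align: bool = True
    flip_z: bool = False
    axis_override: list[float] | None = None
    exclude_hetero: bool = True
    exclude_waters: bool = True
    require_protonated: bool = True
    # hydropathic-index noise
    add_noise: bool = True
    noise_sigma: float = 0.001
    noise_seed: int = 0
    # pore-axis grid
    z_step: float = 0.5
    z_range: list[float] | None = None
    nu_mode: str = "nearest"
    # radial sampling
    k_alpha: int = 800
    # packing fits
    o_mode: str = "tangent"
    eps_asym: float = 0.01
    aicc: bool = False
    n_boot: int = 100
    bootstrap: bool = False
    # scaling analysis
    pc_threshold: float = 0.97
    x_axis: str = "physical_l"
    out_dir: str = "porescale_run"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = {k: v for k, v in raw.items() if k not in cls.__dataclass_fields__}
        cfg = cls(**known)
        cfg.extra.update(unknown)
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        from . import __version__

        return {"config": self.to_dict(), "config_hash": self.hash(),
                "porescale_version": __version__}
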