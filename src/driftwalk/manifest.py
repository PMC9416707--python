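"""Run manifests: everything needed to reproduce a simulation bit-exactly."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from datetime import datetime, timezone

from . import __version__
from .structure import BinaryStructure
from .walk import SimulationConfig


@dataclass
class RunManifest:
    """Resolved configuration, structure checksum and software version."""

    config: dict
    structure_checksum: str
    seed: int | None
    version: str
    created: str

    @classmethod
    def create(cls, structure: BinaryStructure, config: SimulationConfig) -> "RunManifest":
        cfg = config.to_dict()
        return cls(
            config=cfg,
            structure_checksum=structure.checksum(),
            seed=cfg["seed"],
            version=__version__,
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(asdict(self), indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        c = self.config
        return SimulationConfig(
            sigma=c["sigma"],
            drift=(c["lambda_x"], c["lambda_y"]),
            n_trajectories=c["n_trajectories"],
            n_steps=c["n_steps"],
            seed=c["seed"],
        )

    def matches_structure(self, structure: BinaryStructure) -> bool:
        return structure.checksum() == self.structure_checksum
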