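"""Run configuration: every survey/design threshold in one serializable place.

The defaults are the conventions the method was established with; each is a
plain field so alternative cutoffs can be explored from a YAML file without
touching code.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
import yaml

from .bridge_survey import DEFAULT_BIN_EDGES


@dataclass
class RunConfig:
    # pre-filter cascade
    rsa_min: float = 0.35          # fraction; surface residues only
    z_b_min: float = 0.0           # above-average B-factor (flexibility)
    z_rwcn_min: float = 0.0        # below-average packing density
    cons_max: float = 4.0          # ConSurf grade strictly below
    # bridge detection and neighborhood
    bridge_atom_cutoff: float = 4.0   # A, side-chain contact defining a bridge
    neighbor_radius: float = 15.0     # A, CA-CA search radius around a position
    # orientation and sequence rules
    angle_cutoff: float = 110.0       # deg; at least one pseudo-angle below
    angle_distance_gate: float = 7.0  # A; the angle rule applies beyond this
    seq_sep_min: int = 5              # residues; intra-chain pairs need at least
    # exposure classes
    exposed_hi: float = 0.35
    exposed_lo: float = 0.25
    buried_max: float = 0.09
    # pair-index distance bins
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "rsa_min", "bridge_atom_cutoff", "neighbor_radius", "angle_cutoff",
            "angle_distance_gate", "exposed_hi", "exposed_lo", "buried_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.bin_edges = tuple(float(e) for e in self.bin_edges)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bin_edges"] = list(d["bin_edges"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def digest(self) -> str:
        """Short content hash naming this configuration in output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
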