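"""Structured run configuration: YAML round-trip and presets.

A RunConfig aggregates everything a simulation run needs — chain length,
lattice, looping rule, schedule — and serializes to/from YAML so that a
run is reproducible from (config, seed, code version) alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .lattice import LatticeParams
from .loops import DomainLayout, LoopingParams, build_domain_layout
from .protocol import ProtocolParams

__all__ = ["RunConfig", "load_config", "test_preset", "paper_preset"]


@dataclass(frozen=True)
class RunConfig:
    N: int = 105
    lattice: LatticeParams = field(default_factory=lambda: LatticeParams(L=64))
    looping: LoopingParams = field(default_factory=LoopingParams)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    label: str = "run"

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N >= 2 required")

    def layout(self) -> DomainLayout | None:
        if self.looping.mode != "domain_adapted":
            return None
        return build_domain_layout(self.N, self.looping.block_size)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "label": self.label,
            "lattice": asdict(self.lattice),
            "looping": asdict(self.looping),
            "protocol": asdict(self.protocol),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for section, typ in (("lattice", LatticeParams),
                             ("looping", LoopingParams),
                             ("protocol", ProtocolParams)):
            if section in data:
                payload = data[section]
                try:
                    data[section] = typ(**payload)
                except TypeError as exc:
                    raise ValueError(f"bad config section {section!r}: {exc}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValueError(f"bad config: {exc}")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        path = Path(source)
        data = yaml.safe_load(path.read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{source}: config must be a mapping")
        return cls.from_dict(data)

    def fingerprint(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, protocol=replace(self.protocol, seed=seed))


def load_config(path) -> RunConfig:
    return RunConfig.from_yaml(path)


def test_preset(seed: int = 0, mode: str = "uniform_adapted") -> RunConfig:
    """Reduced desk-scale system: a 105-monomer chain (one tenth of the
    full-scale polymer) on an L=64 lattice, with the contour cutoff and
    domain block size scaled to 5 monomers (~5% of the chain, as at full
    scale).  The bond lifetime is scaled to T_bond=1000 MCS so that a
    desk-length run still spans ~100 bond generations (the full-scale
    schedule spans ~10^4), keeping the loop population annealed rather
    than quenched; equilibration and sampling are shortened accordingly.
    """
    return RunConfig(
        N=105,
        lattice=LatticeParams(L=64),
        looping=LoopingParams(mode=mode, p_short=0.12, p_long=0.04,
                              short_cutoff=5, block_size=5, T_bond=1000.0),
        protocol=ProtocolParams(equil1_mcs=20_000, equil2_mcs=80_000,
                                save_interval=4_000, n_conformations=30,
                                seed=seed),
        label="test-preset",
    )


def paper_preset(seed: int = 0, mode: str = "uniform_adapted") -> RunConfig:
    """Full-scale system: 1050 monomers on an L=500 lattice, 50-monomer
    cutoff/blocks, T_bond=8000 MCS, two 1e8-MCS equilibration phases and
    >= 1000 conformations saved every 1e7 MCS.  Cluster-scale: budget
    hours-to-days of CPU, not minutes."""
    return RunConfig(
        N=1050,
        lattice=LatticeParams(L=500),
        looping=LoopingParams(mode=mode, p_short=0.12, p_long=0.04,
                              short_cutoff=50, block_size=50, T_bond=8000.0),
        protocol=ProtocolParams(equil1_mcs=100_000_000,
                                equil2_mcs=100_000_000,
                                save_interval=10_000_000,
                                n_conformations=1000, seed=seed),
        label="full-scale",
    )
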