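"""Screen configuration: one object holding every tunable, YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .cavities import GridSpec
from .chem import HYDROPHOBIC_DEFAULT, LARGE_HYDROPHOBIC_TARGETS, AminoAcidTable


class ConfigError(ValueError):
    pass


@dataclass
class ScreenConfig:
    """All tunables of the short-loop screen.

    The pipeline itself is deterministic; seed is reserved for future
    stochastic extensions and recorded in reports for provenance.
    """

    # cavity grid
    spacing: float = 0.6  # A
    probe_in: float = 1.4  # A, water-sized probe
    probe_out: float = 4.0  # A, bulk-solvent probe
    min_volume: float = 5.0  # A^3, smallest reported cavity
    contact_distance: float = 5.0  # A, cavity lining cutoff
    voxel_budget: int = 400_000_000
    include_hetero: bool = False
    # loop band
    loop_min_len: int = 5
    loop_max_len: int = 7
    require_both_flanks: bool = True
    min_flank_len: int = 3
    flank_extension: int = 2  # residues a hydrophobic run may extend into flanks
    # sensitive-residue thresholds
    max_sidechain_volume: float = 140.0  # A^3
    min_cavity_volume: float = 100.0  # A^3
    # mutation proposals
    targets: list[str] = field(default_factory=lambda: list(LARGE_HYDROPHOBIC_TARGETS))
    clash_factor: float = 0.7
    clash_cap: int = 10
    # chemistry
    hydrophobic_set: list[str] = field(default_factory=lambda: sorted(HYDROPHOBIC_DEFAULT))
    # input handling
    chain: str | None = None
    ss_override: str | None = None  # path to a per-chain HEC string file
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loop_min_len > self.loop_max_len:
            raise ConfigError(
                f"loop_min_len {self.loop_min_len} > loop_max_len {self.loop_max_len}"
            )
        if not (self.probe_out > self.probe_in > 0):
            raise ConfigError("need probe_out > probe_in > 0")
        if self.spacing <= 0:
            raise ConfigError("spacing must be positive")

    def grid(self) -> GridSpec:
        return GridSpec(
            spacing=self.spacing,
            probe_in=self.probe_in,
            probe_out=self.probe_out,
            voxel_budget=self.voxel_budget,
        )

    def table(self) -> AminoAcidTable:
        return AminoAcidTable().with_hydrophobic(set(self.hydrophobic_set))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScreenConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "ScreenConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
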