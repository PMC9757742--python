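"""Simulation configuration.

Every named model constant with its standard default lives here; a YAML file
with the same keys can override any of them.  Defaults follow the reference
parameterization: edge survival probability 0.95, compatibility threshold
0.55, 4500 species seeded per fully natural cell, adaptation lottery 0.001
with factor 0.01, linear land-use response, 100 burn-in steps with webs
rebuilt every 10.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["SimConfig"]

DEFAULT_POOL_COUNTS = {
    "mammal": 5513,
    "amphibian": 7302,
    "bird": 10425,
    "reptile": 10038,
}


@dataclass
class SimConfig:
    # niche calibration
    p_thresh: float = 0.95
    #: immunity / persistence cutoff on the combined extinction probability
    p_ext_cutoff: float = 0.05
    # species creation
    pool_counts: dict = field(default_factory=lambda: dict(DEFAULT_POOL_COUNTS))
    norm_pairs: int = 1_000_000
    ratio_min_records: int = 20
    # web assembly
    c_f_thresh: float = 0.55
    species_per_cell: int = 4500
    # burn-in and clocks
    burn_in_steps: int = 100
    rebuild_every: int = 10
    calibration_months: int = 60
    years: int = 80
    # adaptation
    p_adp: float = 0.001
    C_adp: float = 0.01
    # land use
    S_LUC: float = 0.0
    V_LUC: float = 0.0
    # dispersal clock: "yearly", "monthly" or "none"
    dispersal: str = "yearly"
    # experiment
    replicates: int = 1
    arms: str = "both"  # both | coext | control

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        checks = [
            (0.5 < self.p_thresh < 1.0, "p_thresh must lie in (0.5, 1)"),
            (0.0 <= self.p_ext_cutoff <= 1.0, "p_ext_cutoff must lie in [0, 1]"),
            (0.0 < self.c_f_thresh < 1.0, "c_f_thresh must lie in (0, 1)"),
            (self.species_per_cell >= 0, "species_per_cell must be >= 0"),
            (self.burn_in_steps >= 0, "burn_in_steps must be >= 0"),
            (self.rebuild_every >= 1, "rebuild_every must be >= 1"),
            (self.calibration_months >= 1, "calibration_months must be >= 1"),
            (self.years >= 0, "years must be >= 0"),
            (0.0 <= self.p_adp <= 1.0, "p_adp must lie in [0, 1]"),
            (self.C_adp >= 0.0, "C_adp must be >= 0"),
            (-1.0 <= self.S_LUC <= 1.0, "S_LUC must lie in [-1, 1]"),
            (0.0 <= self.V_LUC <= 1.0, "V_LUC must lie in [0, 1]"),
            (self.dispersal in {"yearly", "monthly", "none"},
             "dispersal must be yearly, monthly or none"),
            (self.replicates >= 1, "replicates must be >= 1"),
            (self.arms in {"both", "coext", "control"},
             "arms must be both, coext or control"),
            (self.norm_pairs >= 2, "norm_pairs must be >= 2"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
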