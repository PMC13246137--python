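"""Run configuration: representation, solver, guess, thresholds.

Defaults follow the conventions used throughout this package: convergence
when the energy change drops below 1e-8 Hartree and both subsystem error
norms drop below 1e-8, DIIS subspace capped at 15, no level shifting or
damping unless requested.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .basis import HP, HPSTAR, REPRESENTATIONS, SD

SOLVERS = ("roothaan", "diis", "gdm", "trah", "diis_gdm_hybrid", "stepwise")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    fixture: str = None
    xyz_path: str = None
    charge: int = 0
    quantum_tags: object = "all-H"
    representation: str = SD
    solver: str = "diis"
    guess_electronic: str = "sad"
    guess_nuclear: str = "sad"
    nuclear_block_core: bool = True
    guess_perturbation: float = 0.0
    e_tol: float = 1e-8
    g_tol: float = 1e-8
    max_iter: int = 200
    diis_cap: int = 15
    seed: int = 0
    shared_protonic_layout: bool = False
    level_shift: float = 0.0
    damping: float = 0.0
    protonic_n_s: int = 4
    protonic_n_p: int = 3
    protonic_alpha0: float = 4.0
    protonic_beta: float = 2.5
    output: str = None
    guess_label: str = field(default="", repr=False)

    def validate(self):
        if self.representation not in REPRESENTATIONS:
            raise ConfigError(f"unknown representation {self.representation!r}")
        if self.solver not in SOLVERS:
            raise ConfigError(f"unknown solver {self.solver!r}")
        if self.solver == "trah" and self.representation in (HP, HPSTAR):
            raise ConfigError("the TRAH solver supports only the SD representation")
        if self.e_tol <= 0 or self.g_tol <= 0:
            raise ConfigError("convergence thresholds must be positive")
        if self.max_iter <= 0:
            raise ConfigError("max_iter must be positive")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("guess_label", None)
        return d

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
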