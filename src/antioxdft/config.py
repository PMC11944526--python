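"""Declarative run configuration (TOML), validated strictly: unknown keys
are rejected rather than ignored."""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict


class QtaimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tolerance: float = 1e-8           # |grad rho| convergence, a.u.
    rho_vdw_cutoff: float = 0.015     # weak H-bond vs van der Waals, a.u.
    be_slope: float = -223.08         # kcal/mol per a.u. of density
    be_intercept: float = 0.7423      # kcal/mol
    max_seed_length_angstrom: float = 3.5
    min_seed_angle_deg: float = 90.0


class MepConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    isovalue: float = 4.0e-4          # electrons/Bohr^3
    polar_threshold: Optional[float] = None  # a.u.; default: surface mean |V|


class ThermoConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference_set: str = "explicit"   # names the H*/H+/e- enthalpies in use


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mode: Literal["qtaim", "descriptors", "mechanism", "fixtures"] = "qtaim"
    inputs: list[str] = []
    rounding: Literal["full", "table"] = "full"
    seed: int = 0
    out_dir: str = "results"
    qtaim: QtaimConfig = QtaimConfig()
    mep: MepConfig = MepConfig()
    thermo: ThermoConfig = ThermoConfig()

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        return cls.model_validate(data)
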