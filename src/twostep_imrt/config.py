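"""Validated run configuration for the planning/adaptation pipeline.

All protocol constants live here: prescriptions (PTV 60.1 Gy and Boost
74 Gy in 33 fractions), the margin rules (10 mm, 7 mm posterior, 5 mm),
the 4 mm MLC leaves, the beam set, the optimizer settings (25 weight
iterations), the beta*-table grid, the requirement set and the isodose
reference dose.  Unknown keys are rejected on load.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Prescriptions(_Strict):
    ptv_gy: float = 60.1
    boost_gy: float = 74.0
    fractions: int = 33

    @model_validator(mode="after")
    def _positive(self):
        if self.ptv_gy <= 0 or self.boost_gy <= 0 or self.fractions < 1:
            raise ValueError("prescriptions must be positive")
        return self


class Margins(_Strict):
    ptv_mm: float = 10.0
    ptv_posterior_mm: float = 7.0
    boost_mm: float = 5.0

    @model_validator(mode="after")
    def _nonneg(self):
        if min(self.ptv_mm, self.ptv_posterior_mm, self.boost_mm) < 0:
            raise ValueError("margins must be >= 0")
        return self


class MLC(_Strict):
    leaf_width_mm: float = 4.0
    field_half_width_mm: float = 200.0


class Beams(_Strict):
    n_angles: int = Field(default=36, ge=3)


class Optimizer(_Strict):
    weight_iterations: int = Field(default=25, ge=0)
    leaf_iterations: int = Field(default=1, ge=0)
    leaf_step_mm: float = Field(default=2.0, gt=0)


class BetaTableGrid(_Strict):
    rho_min: float = 0.05
    rho_max: float = 0.6
    n_rho: int = 12
    gammas: list[float] = Field(default_factory=lambda: [0.0, 0.1, 0.2, 0.3])


class RequirementRow(_Strict):
    label: str
    structure: str
    metric: str
    lower: float | None = None
    upper: float | None = None


class RunConfig(_Strict):
    prescriptions: Prescriptions = Field(default_factory=Prescriptions)
    margins: Margins = Field(default_factory=Margins)
    mlc: MLC = Field(default_factory=MLC)
    beams: Beams = Field(default_factory=Beams)
    optimizer: Optimizer = Field(default_factory=Optimizer)
    beta_table: BetaTableGrid = Field(default_factory=BetaTableGrid)
    requirements: list[RequirementRow] | None = None  # None -> protocol default
    reference_dose_gy: float = 76.2
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


__all__ = ["RunConfig"]
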