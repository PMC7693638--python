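"""Structured run configuration (JSON/YAML) for the CLI pipeline.

Lengths in the file are mm (the unit of the chip drawings), pore geometry in
um, pressures in mbar, flows in uL/min; everything is converted to SI when
the config is lowered to the domain objects. Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import presets
from .hydraulics import (
    BoundaryCondition,
    ChannelGeometry,
    FluidProps,
    MembraneSpec,
    NetworkConfig,
)
from .units import mbar_to_pa, ul_min_to_m3_s


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FluidBlock(_Block):
    viscosity_pa_s: float = Field(1.0e-3, gt=0)
    density_kg_m3: float = Field(1000.0, gt=0)

    def to_domain(self) -> FluidProps:
        return FluidProps(self.viscosity_pa_s, self.density_kg_m3)


class ChannelBlock(_Block):
    width_mm: float = Field(gt=0)
    height_mm: float = Field(gt=0)
    length_mm: float = Field(gt=0)
    well_span_mm: float = Field(gt=0)
    well_start_mm: Optional[float] = Field(None, ge=0)

    def to_domain(self) -> ChannelGeometry:
        return ChannelGeometry(
            width_b=self.width_mm * 1e-3,
            height_h=self.height_mm * 1e-3,
            length=self.length_mm * 1e-3,
            well_span=self.well_span_mm * 1e-3,
            well_start=None if self.well_start_mm is None else self.well_start_mm * 1e-3,
        )


class MembraneBlock(_Block):
    pore_radius_um: float = Field(1.5, gt=0)
    thickness_um: float = Field(10.0, gt=0)
    #: give either the pore areal density or the open-area fraction
    pore_density_per_cm2: Optional[float] = Field(None, gt=0)
    porosity: Optional[float] = Field(None, gt=0, lt=1)
    area_mm2: float = Field(27.0, gt=0)

    @model_validator(mode="after")
    def _one_density(self) -> "MembraneBlock":
        if self.pore_density_per_cm2 is not None and self.porosity is not None:
            raise ValueError("give pore_density_per_cm2 or porosity, not both")
        return self

    def to_domain(self) -> MembraneSpec:
        r = self.pore_radius_um * 1e-6
        if self.porosity is not None:
            return MembraneSpec.from_porosity(
                r, self.thickness_um * 1e-6, self.area_mm2 * 1e-6, self.porosity
            )
        density_cm2 = self.pore_density_per_cm2 if self.pore_density_per_cm2 is not None else 2e6
        return MembraneSpec(
            pore_radius=r,
            thickness=self.thickness_um * 1e-6,
            area=self.area_mm2 * 1e-6,
            pore_density=density_cm2 * 1e4,
        )


class BoundaryBlock(_Block):
    kind: Literal["pressure", "flow"]
    pressure_mbar: Optional[float] = None
    flow_ul_min: Optional[float] = None

    @model_validator(mode="after")
    def _value_matches_kind(self) -> "BoundaryBlock":
        if self.kind == "pressure" and self.pressure_mbar is None:
            raise ValueError("pressure boundary needs pressure_mbar")
        if self.kind == "flow" and self.flow_ul_min is None:
            raise ValueError("flow boundary needs flow_ul_min")
        return self

    def to_domain(self) -> BoundaryCondition:
        if self.kind == "pressure":
            return BoundaryCondition("pressure", mbar_to_pa(self.pressure_mbar))
        return BoundaryCondition("flow", ul_min_to_m3_s(self.flow_ul_min))


class NetworkBlock(_Block):
    n_segments: int = Field(64, ge=1)
    apical: BoundaryBlock = BoundaryBlock(kind="flow", flow_ul_min=100.0)
    basal: BoundaryBlock = BoundaryBlock(kind="flow", flow_ul_min=100.0)
    apical_outlet_mbar: Optional[float] = 0.0
    basal_outlet_mbar: Optional[float] = 0.0

    def to_domain(self) -> NetworkConfig:
        return NetworkConfig(
            apical_inlet=self.apical.to_domain(),
            basal_inlet=self.basal.to_domain(),
            n_segments=self.n_segments,
            apical_outlet_pressure=(
                None if self.apical_outlet_mbar is None else mbar_to_pa(self.apical_outlet_mbar)
            ),
            basal_outlet_pressure=(
                None if self.basal_outlet_mbar is None else mbar_to_pa(self.basal_outlet_mbar)
            ),
        )


class PlanformBlock(_Block):
    semi_axis_b_mm: float = Field(3.0, gt=0)
    semi_axis_c_mm: float = Field(2.25, gt=0)


def _default_channel(geom) -> ChannelBlock:
    return ChannelBlock(
        width_mm=geom.width_b * 1e3,
        height_mm=geom.height_h * 1e3,
        length_mm=geom.length * 1e3,
        well_span_mm=geom.well_span * 1e3,
        well_start_mm=geom.well_start_resolved * 1e3,
    )


class RunConfig(_Block):
    """Full run configuration; defaults are the reference chip."""

    fluid: FluidBlock = FluidBlock()
    apical: ChannelBlock = _default_channel(presets.APICAL_CHANNEL)
    basal: ChannelBlock = _default_channel(presets.BASAL_CHANNEL)
    membrane: MembraneBlock = MembraneBlock()
    network: NetworkBlock = NetworkBlock()
    planform: PlanformBlock = PlanformBlock()
    #: flows (uL/min) at which design reports wall shear stress
    shear_flows_ul_min: list[float] = Field(default_factory=lambda: [100.0])
    seed: int = 0

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML or JSON config file; ``None`` yields the defaults."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    return RunConfig.model_validate(data)
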