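"""Documented default parameter set for the reference chip.

The reference device is characterized by: culture-well widths 6 mm (apical)
and 4.5 mm (basal), channel height 0.5 mm, water as working fluid, and a
3 um-pore track-etched culture membrane. Everything else a lumped model needs
is closed here with manufacturer-typical and chip-format-typical values (see
docs/methods.md for rationale); every value is overridable
through the config layer and every solver run records the set used.
"""

from __future__ import annotations

from .hydraulics import (
    BoundaryCondition,
    ChannelGeometry,
    FluidProps,
    MembraneSpec,
    NetworkConfig,
)
from .mechanics import MembranePlanform
from .units import ul_min_to_m3_s

#: Water at room temperature.
WATER = FluidProps(viscosity=1.0e-3, density=1000.0)

#: Transwell membrane area used for TEER normalization (cm^2).
TRANSWELL_AREA_CM2 = 0.336

# Chip format: 45 mm channel runs with the (crossing) culture well offset
# 6 mm from the inlet end. The well overlap is 6 mm x 4.5 mm, so each
# channel's well span equals the other channel's width.
CHANNEL_LENGTH_M = 45e-3
WELL_START_M = 6e-3

APICAL_CHANNEL = ChannelGeometry(
    width_b=6e-3, height_h=0.5e-3, length=CHANNEL_LENGTH_M,
    well_span=4.5e-3, well_start=WELL_START_M,
)
BASAL_CHANNEL = ChannelGeometry(
    width_b=4.5e-3, height_h=0.5e-3, length=CHANNEL_LENGTH_M,
    well_span=6e-3, well_start=WELL_START_M,
)

#: Culture-well overlap footprint, 6 mm x 4.5 mm.
MEMBRANE_AREA_M2 = 6e-3 * 4.5e-3

#: 3 um-pore track-etched insert: pore radius 1.5 um, thickness 10 um,
#: pore density 2e6 cm^-2 (open-area fraction ~0.14).
MEMBRANE = MembraneSpec(
    pore_radius=1.5e-6,
    thickness=10e-6,
    area=MEMBRANE_AREA_M2,
    pore_density=2e6 * 1e4,  # per m^2
)

#: Membrane planform semi-axes for strain analysis: half the culture-well
#: widths (b = 3 mm, c = 2.25 mm).
PLANFORM = MembranePlanform(semi_axis_b=3.0, semi_axis_c=2.25)


def flow_driven_network(
    q_apical_ul_min: float = 100.0,
    q_basal_ul_min: float = 100.0,
    n_segments: int = 64,
) -> NetworkConfig:
    """Both inlets flow-driven (syringe/recirculation operation), outlets
    draining to open reservoirs at atmospheric pressure."""
    return NetworkConfig(
        apical_inlet=BoundaryCondition("flow", ul_min_to_m3_s(q_apical_ul_min)),
        basal_inlet=BoundaryCondition("flow", ul_min_to_m3_s(q_basal_ul_min)),
        n_segments=n_segments,
    )


def pressure_driven_network(
    p_apical_mbar: float = 20.0,
    p_basal_mbar: float = 80.0,
    n_segments: int = 64,
) -> NetworkConfig:
    """Pressure-controller operation; defaults are the glomerular filtration
    protocol (basal 80 mbar ~ 60 mmHg, apical 20 mbar ~ 15 mmHg)."""
    return NetworkConfig(
        apical_inlet=BoundaryCondition("pressure", p_apical_mbar * 100.0),
        basal_inlet=BoundaryCondition("pressure", p_basal_mbar * 100.0),
        n_segments=n_segments,
    )
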