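"""Lumped-parameter hydraulic model of a two-channel membrane chip.

The chip is treated as an electrical circuit through the hydraulic-electric
analogy (pressure <-> voltage, volumetric flow <-> current, hydraulic
resistance <-> resistance). Each microchannel is a chain of axial resistors;
over the culture well the two channels are bridged by the distributed
resistance of the porous membrane, so a basal-to-apical pressure excess drives
transmembrane ultrafiltration, exactly as plasma is filtered across the
glomerular filtration barrier.

Membrane model
--------------
Each pore is a circular pipe of radius ``R`` and length ``L`` (the membrane
thickness), so by Hagen-Poiseuille a single pore has resistance

    R_pore = 8 mu L / (pi R^4).

With ``rho_pore`` pores per unit area on a wetted area ``A`` the whole
membrane is ``A rho_pore`` such pipes in parallel:

    R_memb = R_pore / (A rho_pore),

equivalent to a Darcy medium of permeability

    k = pi rho_pore R^4 / 8        (units m^2; k = phi R^2/8 with porosity
                                    fraction phi = rho_pore pi R^2),

so that R_memb = mu L / (k A) identically. Note ``rho_pore`` is a pore
*areal density* (m^-2); the open-area *fraction* is exposed as
:attr:`MembraneSpec.porosity`.

Channels are closed with the parallel-plate Poiseuille law
``R = 12 mu l / (b h^3)`` (shallow rectangular ducts, h << b), consistent
with the plane-Poiseuille wall-shear formula ``tau = 6 mu Q / (b h^2)``; the
exact rectangular-duct series correction is available via
``channel_resistance(..., exact=True)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, DomainError, FitError

__all__ = [
    "FluidProps",
    "ChannelGeometry",
    "MembraneSpec",
    "HydraulicResistance",
    "BoundaryCondition",
    "NetworkConfig",
    "FlowSolution",
    "pore_resistance",
    "membrane_resistance",
    "permeability",
    "channel_resistance",
    "wall_shear_stress",
    "solve_coupled_network",
    "transmembrane_flow",
    "fit_pq_line",
    "fit_membrane_permeability",
    "PQFit",
]


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise DomainError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class FluidProps:
    """Newtonian working fluid (defaults in :mod:`mpsflow.presets` are water)."""

    viscosity: float  # dynamic viscosity, Pa*s
    density: float = 1000.0  # kg/m^3

    def __post_init__(self) -> None:
        _require_positive("viscosity", self.viscosity)
        _require_positive("density", self.density)


@dataclass(frozen=True)
class ChannelGeometry:
    """Shallow rectangular channel with a culture-well region.

    All lengths in metres. ``width_b`` is the channel width at the culture
    well, ``well_span`` the axial extent of the membrane-exposed (culture
    well) region and ``well_start`` its axial offset from the inlet
    (``None`` centres the well).
    """

    width_b: float
    height_h: float
    length: float
    well_span: float
    well_start: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("width_b", "height_h", "length", "well_span"):
            _require_positive(name, getattr(self, name))
        if self.height_h > self.width_b:
            raise DomainError(
                "height_h must be <= width_b (shallow-channel assumption)"
            )
        if self.well_span > self.length:
            raise DomainError("well_span must be <= length")
        if self.well_start is not None:
            if self.well_start < 0:
                raise DomainError("well_start must be >= 0")
            if self.well_start + self.well_span > self.length:
                raise DomainError("well_start + well_span must be <= length")

    @property
    def well_start_resolved(self) -> float:
        if self.well_start is None:
            return 0.5 * (self.length - self.well_span)
        return self.well_start


@dataclass(frozen=True)
class MembraneSpec:
    """Track-etched porous membrane: parallel circular pores.

    ``pore_density`` is the number of pores per unit area (m^-2); the
    open-area fraction ``porosity = pore_density * pi * pore_radius^2`` must
    lie in (0, 1). Construct from a porosity fraction with
    :meth:`from_porosity`.
    """

    pore_radius: float  # m
    thickness: float  # m
    area: float  # wetted (well-overlap) area, m^2
    pore_density: float  # pores per m^2

    def __post_init__(self) -> None:
        _require_positive("pore_radius", self.pore_radius)
        _require_positive("thickness", self.thickness)
        _require_positive("area", self.area)
        _require_positive("pore_density", self.pore_density)
        if not (0.0 < self.porosity < 1.0):
            raise DomainError(
                f"porosity (pore_density*pi*R^2) must be in (0, 1), "
                f"got {self.porosity!r}"
            )

    @property
    def porosity(self) -> float:
        """Open-area fraction, dimensionless."""
        return self.pore_density * math.pi * self.pore_radius**2

    @classmethod
    def from_porosity(
        cls, pore_radius: float, thickness: float, area: float, porosity: float
    ) -> "MembraneSpec":
        _require_positive("pore_radius", pore_radius)
        _require_positive("porosity", porosity)
        density = porosity / (math.pi * pore_radius**2)
        return cls(pore_radius, thickness, area, density)

    def with_permeability(self, k: float) -> "MembraneSpec":
        """Same membrane with pore density adjusted to give permeability ``k``."""
        _require_positive("k", k)
        return replace(self, pore_density=8.0 * k / (math.pi * self.pore_radius**4))


Scope = Literal["single_pore", "whole_membrane", "channel_segment"]


@dataclass(frozen=True)
class HydraulicResistance:
    value: float  # Pa*s/m^3
    scope: Scope

    def __post_init__(self) -> None:
        _require_positive("value", self.value)


def pore_resistance(membrane: MembraneSpec, fluid: FluidProps) -> HydraulicResistance:
    """Hagen-Poiseuille resistance of a single cylindrical pore,
    R_pore = 8 mu L / (pi R^4)."""
    value = (
        8.0
        * fluid.viscosity
        * membrane.thickness
        / (math.pi * membrane.pore_radius**4)
    )
    return HydraulicResistance(value, "single_pore")


def membrane_resistance(
    membrane: MembraneSpec, fluid: FluidProps
) -> HydraulicResistance:
    """Whole-membrane resistance, R_memb = R_pore / (A rho_pore):
    ``A * rho_pore`` pores in parallel over the wetted area."""
    r_pore = pore_resistance(membrane, fluid).value
    value = r_pore / (membrane.area * membrane.pore_density)
    return HydraulicResistance(value, "whole_membrane")


def permeability(membrane: MembraneSpec) -> float:
    """Darcy permeability of the membrane, k = pi rho_pore R^4 / 8 (m^2).

    Satisfies mu L / (k A) == membrane_resistance exactly (same algebra).
    """
    return math.pi * membrane.pore_density * membrane.pore_radius**4 / 8.0


def _rect_duct_correction(width: float, height: float, n_terms: int = 40) -> float:
    # Fourier-series aspect-ratio factor for a rectangular duct; ->1 as h/b->0.
    s = 0.0
    for m in range(1, 2 * n_terms, 2):
        s += math.tanh(m * math.pi * width / (2.0 * height)) / m**5
    return 1.0 - (192.0 * height) / (math.pi**5 * width) * s


def channel_resistance(
    geometry: ChannelGeometry, fluid: FluidProps, exact: bool = False
) -> HydraulicResistance:
    """Axial resistance of a shallow rectangular channel.

    Parallel-plate Poiseuille closure R = 12 mu l / (b h^3); with
    ``exact=True`` the rectangular-duct series correction is applied.
    """
    value = (
        12.0
        * fluid.viscosity
        * geometry.length
        / (geometry.width_b * geometry.height_h**3)
    )
    if exact:
        value /= _rect_duct_correction(geometry.width_b, geometry.height_h)
    return HydraulicResistance(value, "channel_segment")


def wall_shear_stress(Q: float, geometry: ChannelGeometry, fluid: FluidProps) -> float:
    """Wall shear stress at the membrane, tau = 6 mu Q / (b h^2) (Pa).

    Plane-Poiseuille profile between parallel plates; ``b`` is the channel
    width at the centre of the culture well and ``h`` the channel height.
    """
    if Q < 0:
        raise DomainError("Q must be >= 0")
    return 6.0 * fluid.viscosity * Q / (geometry.width_b * geometry.height_h**2)


# --------------------------------------------------------------------------
# Coupled two-channel network solver
# --------------------------------------------------------------------------

BoundaryKind = Literal["pressure", "flow"]


@dataclass(frozen=True)
class BoundaryCondition:
    """Inlet boundary: an imposed gauge pressure (Pa) or volumetric flow (m^3/s)."""

    kind: BoundaryKind
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("pressure", "flow"):
            raise ConfigurationError(f"unknown boundary kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkConfig:
    """Discretization and boundary conditions for the coupled solve.

    Outlet pressures are gauge; ``None`` seals an outlet (dead-end channel).
    """

    apical_inlet: BoundaryCondition
    basal_inlet: BoundaryCondition
    n_segments: int = 64
    apical_outlet_pressure: Optional[float] = 0.0
    basal_outlet_pressure: Optional[float] = 0.0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ConfigurationError("n_segments must be >= 1")


@dataclass(frozen=True)
class FlowSolution:
    """Nodal pressures and flows of the discretized coupled network.

    Per channel there are ``n + 2`` nodes (inlet, ``n`` well-segment centres,
    outlet) and ``n + 1`` axial links. ``transmembrane_flux`` holds the per-
    segment membrane crossing flow, positive basal->apical (the urinary
    direction in the glomerular configuration). A sealed outlet reports NaN
    pressure and zero flow on the final link.
    """

    node_pressures_apical: np.ndarray  # Pa, length n+2
    node_pressures_basal: np.ndarray
    node_positions_apical: np.ndarray  # m along the channel axis
    node_positions_basal: np.ndarray
    segment_flows_apical: np.ndarray  # m^3/s, length n+1, positive toward outlet
    segment_flows_basal: np.ndarray
    transmembrane_flux: np.ndarray  # m^3/s, length n, positive basal->apical
    parameters: dict = field(default_factory=dict, compare=False)

    @property
    def n_segments(self) -> int:
        return len(self.transmembrane_flux)


def _channel_links(
    geometry: ChannelGeometry, fluid: FluidProps, n: int
) -> tuple[list[float], np.ndarray]:
    """Axial link resistances (inlet->c1, c1->c2, ..., cn->outlet) and node
    positions for a node-centred discretization of the well region."""
    r_per_len = 12.0 * fluid.viscosity / (geometry.width_b * geometry.height_h**3)
    ws = geometry.well_start_resolved
    seg = geometry.well_span / n
    r_seg = r_per_len * seg
    r_up = r_per_len * ws
    r_down = r_per_len * (geometry.length - ws - geometry.well_span)
    links = [r_up + 0.5 * r_seg]
    links += [r_seg] * (n - 1)
    links += [0.5 * r_seg + r_down]
    positions = np.concatenate(
        ([0.0], ws + (np.arange(n) + 0.5) * seg, [geometry.length])
    )
    return links, positions


def solve_coupled_network(
    apical: ChannelGeometry,
    basal: ChannelGeometry,
    membrane: MembraneSpec,
    fluid: FluidProps,
    config: NetworkConfig,
) -> FlowSolution:
    """Solve the coupled two-channel nodal system.

    Channel segments are axial resistors; the membrane couples the two
    channels over the culture-well overlap as ``n`` cross-resistors, each
    carrying 1/n of the wetted area (resistance ``n * R_memb``). The linear
    nodal (Kirchhoff) system is solved densely, so mass is conserved at every
    node to machine precision and the solution is exactly linear in the
    boundary drive.
    """
    n = config.n_segments
    r_m_seg = membrane_resistance(membrane, fluid).value * n

    links_a, pos_a = _channel_links(apical, fluid, n)
    links_b, pos_b = _channel_links(basal, fluid, n)

    n_nodes = 2 * (n + 2)
    off_b = n + 2  # basal node ids follow apical ids

    edges: list[tuple[int, int, float]] = []  # (node_i, node_j, conductance)
    for i, r in enumerate(links_a):
        edges.append((i, i + 1, 1.0 / r) if r > 0 else (i, i + 1, math.inf))
    for i, r in enumerate(links_b):
        edges.append((off_b + i, off_b + i + 1, 1.0 / r if r > 0 else math.inf))
    for i in range(n):  # membrane bridges between well-segment centres
        edges.append((1 + i, off_b + 1 + i, 1.0 / r_m_seg))

    dirichlet: dict[int, float] = {}
    sources = np.zeros(n_nodes)
    sealed_apical = config.apical_outlet_pressure is None
    sealed_basal = config.basal_outlet_pressure is None
    if not sealed_apical:
        dirichlet[n + 1] = float(config.apical_outlet_pressure)
    if not sealed_basal:
        dirichlet[off_b + n + 1] = float(config.basal_outlet_pressure)
    for inlet_node, bc in ((0, config.apical_inlet), (off_b, config.basal_inlet)):
        if bc.kind == "pressure":
            dirichlet[inlet_node] = bc.value
        else:
            sources[inlet_node] = bc.value
    if sealed_apical:
        edges = [e for e in edges if {e[0], e[1]} != {n, n + 1}]
    if sealed_basal:
        edges = [e for e in edges if {e[0], e[1]} != {off_b + n, off_b + n + 1}]

    if not dirichlet:
        raise ConfigurationError(
            "no pressure reference: both channels flow-driven with sealed "
            "outlets leaves the pressure field undetermined"
        )

    free = [
        i
        for i in range(n_nodes)
        if i not in dirichlet
        and not (sealed_apical and i == n + 1)
        and not (sealed_basal and i == off_b + n + 1)
    ]
    index = {node: k for k, node in enumerate(free)}
    G = np.zeros((len(free), len(free)))
    rhs = np.array([sources[i] for i in free])
    for i, j, g in edges:
        if not math.isfinite(g):
            raise ConfigurationError("zero-resistance link: merge nodes instead")
        for a, b in ((i, j), (j, i)):
            if a in index:
                G[index[a], index[a]] += g
                if b in index:
                    G[index[a], index[b]] -= g
                else:
                    rhs[index[a]] += g * dirichlet[b]
    try:
        p_free = np.linalg.solve(G, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(f"singular hydraulic network: {exc}") from exc

    pressures = np.full(n_nodes, np.nan)
    for node, p in dirichlet.items():
        pressures[node] = p
    for node, k in index.items():
        pressures[node] = p_free[k]

    def _link_flows(offset: int, links: Sequence[float], sealed: bool) -> np.ndarray:
        flows = np.zeros(len(links))
        for i, r in enumerate(links):
            if sealed and i == len(links) - 1:
                flows[i] = 0.0
            else:
                flows[i] = (pressures[offset + i] - pressures[offset + i + 1]) / r
        return flows

    flows_a = _link_flows(0, links_a, sealed_apical)
    flows_b = _link_flows(off_b, links_b, sealed_basal)
    q_tm = np.array(
        [
            (pressures[off_b + 1 + i] - pressures[1 + i]) / r_m_seg
            for i in range(n)
        ]
    )

    params = {
        "n_segments": n,
        "viscosity_pa_s": fluid.viscosity,
        "density_kg_m3": fluid.density,
        "membrane_pore_radius_m": membrane.pore_radius,
        "membrane_thickness_m": membrane.thickness,
        "membrane_pore_density_per_m2": membrane.pore_density,
        "membrane_porosity": membrane.porosity,
        "membrane_area_m2": membrane.area,
        "membrane_resistance_pa_s_m3": membrane_resistance(membrane, fluid).value,
        "membrane_permeability_m2": permeability(membrane),
        "apical_geometry": apical,
        "basal_geometry": basal,
        "config": config,
    }
    return FlowSolution(
        node_pressures_apical=pressures[: n + 2],
        node_pressures_basal=pressures[off_b:],
        node_positions_apical=pos_a,
        node_positions_basal=pos_b,
        segment_flows_apical=flows_a,
        segment_flows_basal=flows_b,
        transmembrane_flux=q_tm,
        parameters=params,
    )


def transmembrane_flow(solution: FlowSolution) -> float:
    """Net ultrafiltration flow (m^3/s, positive basal->apical): the sum of
    per-segment membrane fluxes, equal to basal inlet minus basal outlet flow
    to solver tolerance."""
    return float(np.sum(solution.transmembrane_flux))


# --------------------------------------------------------------------------
# CSV interfaces
# --------------------------------------------------------------------------


def export_solution(solution: FlowSolution, path) -> None:
    """Write the nodal solution as CSV: node index, axial position (mm) and
    pressure (Pa) per channel, and per-segment transmembrane flux (blank on
    the non-segment rows)."""
    import pandas as pd

    n_nodes = len(solution.node_pressures_apical)
    flux = np.full(n_nodes, np.nan)
    flux[1 : solution.n_segments + 1] = solution.transmembrane_flux
    pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "position_apical_mm": solution.node_positions_apical * 1e3,
            "pressure_apical_pa": solution.node_pressures_apical,
            "position_basal_mm": solution.node_positions_basal * 1e3,
            "pressure_basal_pa": solution.node_pressures_basal,
            "transmembrane_flux_m3_s": flux,
        }
    ).to_csv(path, index=False)


def read_flow_recordings(path):
    """Read a flow-meter recording CSV (time_s, pressure_mbar, flow_ul_min)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = ["time_s", "pressure_mbar", "flow_ul_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DomainError(f"flow recording CSV {path} missing columns: {missing}")
    return df


def fit_pq_recordings(recordings) -> PQFit:
    """Average each pressure level of a recording table and fit the P-Q line
    in SI units (the bench workflow: mean of a 60 s recording per level)."""
    from .units import mbar_to_pa, ul_min_to_m3_s

    means = recordings.groupby("pressure_mbar")["flow_ul_min"].mean()
    return fit_pq_line(
        [mbar_to_pa(p) for p in means.index],
        [ul_min_to_m3_s(q) for q in means.to_numpy()],
    )


# --------------------------------------------------------------------------
# Fits
# --------------------------------------------------------------------------


class PQFit(NamedTuple):
    resistance: float  # Pa*s/m^3, 1/slope
    slope: float  # m^3/s per Pa
    intercept: float  # m^3/s
    r_squared: float
    degenerate: bool


def fit_pq_line(
    pressures: Sequence[float], flows: Sequence[float]
) -> PQFit:
    """Least-squares line through (P, Q) flow-meter calibration data.

    The fitted hydraulic resistance is 1/slope. Inputs in SI (Pa, m^3/s);
    a zero or negative slope leaves the resistance undefined (``inf``) and
    sets ``degenerate`` with a warning rather than raising, since flat
    recordings are a routine bench failure mode.
    """
    p = np.asarray(pressures, dtype=float)
    q = np.asarray(flows, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise DomainError("pressures and flows must be 1-D and the same length")
    if len(np.unique(p)) < 3:
        raise DomainError("need >= 3 distinct pressures to fit a P-Q line")
    res = stats.linregress(p, q)
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    if slope <= 0 or not math.isfinite(slope):
        warnings.warn("P-Q fit slope <= 0: resistance undefined", stacklevel=2)
        return PQFit(math.inf, slope, float(res.intercept), r2, True)
    return PQFit(1.0 / slope, slope, float(res.intercept), r2, False)


def fit_membrane_permeability(
    q_tm_observed: Sequence[float],
    operating_points: Sequence[NetworkConfig],
    apical: ChannelGeometry,
    basal: ChannelGeometry,
    membrane: MembraneSpec,
    fluid: FluidProps,
) -> float:
    """Estimate membrane permeability k (m^2) from observed ultrafiltration.

    Least-squares over k of the misfit between :func:`solve_coupled_network`
    predictions and the observed transmembrane flows at the given operating
    points. ``membrane`` supplies pore radius, thickness, area and the
    initial k guess. Raises :class:`FitError` when no operating point drives
    any transmembrane flow (k is then unidentifiable).
    """
    q_obs = np.asarray(q_tm_observed, dtype=float)
    if q_obs.ndim != 1 or len(q_obs) != len(operating_points) or len(q_obs) == 0:
        raise DomainError("need one observed Q_tm per operating point (>= 1)")

    def predict(k: float) -> np.ndarray:
        memb_k = membrane.with_permeability(k)
        return np.array(
            [
                transmembrane_flow(
                    solve_coupled_network(apical, basal, memb_k, fluid, cfg)
                )
                for cfg in operating_points
            ]
        )

    k0 = permeability(membrane)
    # porosity must stay < 1: bound k away from the physical packing limit
    k_max = 0.999 * membrane.pore_radius**2 / 8.0
    # below ~1e-18 m^3/s (1e-7 uL/min) predicted flow is numerical noise, far
    # under anything a flow sensor resolves: k is then unidentifiable
    if np.max(np.abs(predict(min(k0, k_max)))) < 1e-18:
        raise FitError(
            "non-identifiable: no operating point produces transmembrane flow"
        )
    scale = max(np.max(np.abs(q_obs)), 1e-30)
    result = optimize.least_squares(
        lambda x: (predict(x[0]) - q_obs) / scale,
        x0=[min(k0, 0.5 * k_max)],
        bounds=([1e-30], [k_max]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=None,
    )
    return float(result.x[0])
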