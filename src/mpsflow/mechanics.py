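"""Bi-axial membrane strain from pressure-deflection sweeps.

When the apical channel is pressurized the culture membrane bulges into the
basal channel; the bulged membrane is approximated as a semi-ellipsoid whose
cap height ``a`` is the measured centre deflection and whose base semi-axes
``b >= c`` are set by the culture-well planform. The cap surface area uses
the Thomsen approximation (exponent p = 1.6075), plus the base ellipse:

    SA(a) = 2 pi [((a b)^p + (a c)^p + (b c)^p) / 3]^(1/p) + pi b c

and the bi-axial surface strain is the fractional area change

    eps_SA(a) = (SA(a) - SA(0)) / SA(0).

SA(0) is evaluated with the *same* formula at a = 0 rather than as the flat
ellipse pi*b*c: the Thomsen term does not vanish at a = 0 (it leaves
2 pi b c (1/3)^(1/p), a ~1% artefact of the approximation), and evaluating
both states with one formula cancels that bias and makes eps_SA(0) = 0 exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "THOMSEN_P",
    "DeflectionRecord",
    "MembranePlanform",
    "StrainCurve",
    "semi_ellipsoid_area",
    "biaxial_strain",
    "deflection_for_strain",
    "strain_sweep",
]

#: Thomsen exponent of the ellipsoid surface-area approximation (fixed).
THOMSEN_P = 1.6075


@dataclass(frozen=True)
class MembranePlanform:
    """Base semi-axes of the bulging membrane (mm), b >= c > 0."""

    semi_axis_b: float
    semi_axis_c: float

    def __post_init__(self) -> None:
        if not (self.semi_axis_b >= self.semi_axis_c > 0):
            raise DomainError("planform requires semi_axis_b >= semi_axis_c > 0")


@dataclass(frozen=True)
class DeflectionRecord:
    """One point of a sweep: applied pressure (mbar) and centre deflection
    (mm, change from the initial focal distance)."""

    applied_pressure: float
    deflection_a: float

    def __post_init__(self) -> None:
        if self.deflection_a < 0:
            raise DomainError("deflection_a must be >= 0")


@dataclass(frozen=True)
class StrainCurve:
    pressures: np.ndarray  # mbar, increasing
    strains: np.ndarray  # dimensionless eps_SA

    def __post_init__(self) -> None:
        if len(self.pressures) != len(self.strains):
            raise DomainError("pressures and strains must be paired")


def semi_ellipsoid_area(a: float, planform: MembranePlanform) -> float:
    """Surface area (mm^2) of the deflected membrane: Thomsen semi-ellipsoid
    cap of height ``a`` over the elliptical base, plus the base ellipse."""
    if a < 0:
        raise DomainError("deflection a must be >= 0")
    b, c = planform.semi_axis_b, planform.semi_axis_c
    p = THOMSEN_P
    cap = 2.0 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)
    return float(cap + np.pi * b * c)


def biaxial_strain(a: float, planform: MembranePlanform) -> float:
    """Bi-axial surface strain eps_SA = (SA(a) - SA(0)) / SA(0)."""
    sa0 = semi_ellipsoid_area(0.0, planform)
    return (semi_ellipsoid_area(a, planform) - sa0) / sa0


def deflection_for_strain(
    target_strain: float, planform: MembranePlanform, a_max: float = 100.0
) -> float:
    """Invert eps_SA(a): the centre deflection (mm) producing a given strain.

    eps_SA is continuous and strictly increasing in ``a``, so the root is
    unique; bracketing then bisection (Brent).
    """
    if target_strain < 0:
        raise DomainError("target_strain must be >= 0")
    if target_strain == 0:
        return 0.0
    hi = min(1.0, a_max)
    while biaxial_strain(hi, planform) < target_strain:
        hi *= 2.0
        if hi > a_max:
            raise DomainError(
                f"target_strain {target_strain} not reached below a={a_max} mm"
            )
    return float(brentq(lambda a: biaxial_strain(a, planform) - target_strain, 0.0, hi))


def strain_sweep(
    records: Sequence[DeflectionRecord], planform: MembranePlanform
) -> StrainCurve:
    """Elementwise strain over a pressure sweep (pressure strictly increasing)."""
    if len(records) < 2:
        raise DomainError("a sweep needs >= 2 records")
    pressures = np.array([r.applied_pressure for r in records], dtype=float)
    if not np.all(np.diff(pressures) > 0):
        raise DomainError("sweep pressures must be strictly increasing (no duplicates)")
    strains = np.array([biaxial_strain(r.deflection_a, planform) for r in records])
    return StrainCurve(pressures=pressures, strains=strains)


def read_deflection_sweep(path) -> list[DeflectionRecord]:
    """Read the deflection CSV dialect (pressure_mbar, deflection_um);
    deflections are converted to mm."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = [c for c in ("pressure_mbar", "deflection_um") if c not in df.columns]
    if missing:
        raise DomainError(f"deflection CSV {path} missing columns: {missing}")
    return [
        DeflectionRecord(float(p), float(d) / 1000.0)
        for p, d in zip(df["pressure_mbar"], df["deflection_um"])
    ]


def write_strain_curve(curve: StrainCurve, path) -> None:
    """Write a strain curve as CSV (pressure_mbar, strain)."""
    import pandas as pd

    pd.DataFrame({"pressure_mbar": curve.pressures, "strain": curve.strains}).to_csv(
        path, index=False
    )
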