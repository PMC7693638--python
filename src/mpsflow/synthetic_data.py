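"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one bench instrument around a known ground truth
(`TrueParams`), so the whole pipeline is testable with no external data and
parameter recovery can be checked against the truth:

- flow-meter recordings of the linear pressure-flow response of a channel
  (additive Gaussian sensor noise, sd as a fraction of full scale);
- focal-distance deflection sweeps of the culture membrane, 0-315 mbar in
  15 mbar steps (additive Gaussian focal noise);
- volt-ohm-meter TEER time courses for podocyte-only, endothelial-only and
  co-culture conditions (logistic coverage growth, additive ohmmeter noise);
- paired apical/basal outflow readouts for albumin and inulin under blank /
  control / S1P-injured conditions (multiplicative log-normal concentration
  noise around per-condition sieving coefficients).

The deflection compliance law is a power law a(P) = c1 * P^c2 chosen only
because it is monotone and passes through the origin; it carries no claim
about membrane physics. Determinism: every generator derives its RNG from
(seed, stream id), so identical (seed, scenario) gives byte-identical CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from types import MappingProxyType
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import presets
from .assays import READOUT_COLUMNS
from .errors import DomainError
from .hydraulics import channel_resistance, permeability
from .mechanics import DeflectionRecord, MembranePlanform, deflection_for_strain
from .units import mbar_to_pa, m3_s_to_ul_min

__all__ = [
    "NoiseModel",
    "TeerGrowth",
    "TrueParams",
    "SyntheticScenario",
    "default_true_params",
    "default_scenario",
    "gen_flow_recordings",
    "gen_deflection_sweep",
    "gen_teer_timecourse",
    "gen_filtration_readouts",
    "write_deflection_csv",
    "materialize_fixtures",
]

_STREAMS = {"flow": 1, "deflection": 2, "teer": 3, "filtration": 4}


@dataclass(frozen=True)
class NoiseModel:
    """Per-instrument noise scales (all >= 0)."""

    flow_sd_frac_fullscale: float = 0.02  # flow sensor, fraction of full scale
    focal_sd_um: float = 2.0  # focal-distance readout, um
    ohm_sd: float = 5.0  # volt-ohm meter, Ohm
    conc_cv: float = 0.10  # concentration readout, coefficient of variation

    def __post_init__(self) -> None:
        for name in ("flow_sd_frac_fullscale", "focal_sd_um", "ohm_sd", "conc_cv"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TeerGrowth:
    """Logistic coverage growth mapped to a TEER plateau."""

    teer_max: float  # Ohm cm^2 at full coverage
    rate: float = 0.9  # 1/day
    midpoint_day: float = 3.5


@dataclass(frozen=True)
class TrueParams:
    """Ground truth behind the generators."""

    resistance_apical: float  # Pa*s/m^3
    resistance_basal: float
    permeability_k: float  # m^2
    compliance_c1: float  # mm / mbar^c2
    compliance_c2: float  # in (0, 1]
    sieving: Mapping[tuple[str, str], float]  # (solute, condition) -> [0, 1]
    teer_growth: Mapping[str, TeerGrowth]
    r_blank_ohm: float = 100.0
    m_area_cm2: float = presets.TRANSWELL_AREA_CM2
    basal_feed_mg_ml: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType({"albumin": 2.0, "inulin": 0.1})
    )
    apical_volume_ul: float = 120.0

    def __post_init__(self) -> None:
        for key, s in self.sieving.items():
            if not (0.0 <= s <= 1.0):
                raise DomainError(f"sieving coefficient {key} must be in [0, 1]")
        if not (0.0 < self.compliance_c2 <= 1.0):
            raise DomainError("compliance_c2 must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int
    noise: NoiseModel = NoiseModel()
    true_params: TrueParams = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.true_params is None:
            object.__setattr__(self, "true_params", default_true_params())

    def rng(self, stream: str, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream], *extra])


def default_true_params(planform: Optional[MembranePlanform] = None) -> TrueParams:
    """Ground truth matching the reference chip defaults.

    The compliance prefactor ``c1`` is set (by inverting the strain formula)
    so that the noiseless sweep reaches 4% bi-axial strain at 315 mbar, the
    maximum the bare membrane experiences in the stretch protocol.
    """
    planform = planform or presets.PLANFORM
    c2 = 0.8
    a_at_4pct = deflection_for_strain(0.04, planform)
    c1 = a_at_4pct / 315.0**c2
    sieving = {
        # cells retard albumin strongly; S1P injury doubles albumin sieving
        ("albumin", "blank"): 0.90,
        ("albumin", "control"): 0.15,
        ("albumin", "S1P"): 0.30,
        # inulin is freely filtered: nearly equal across conditions
        ("inulin", "blank"): 0.90,
        ("inulin", "control"): 0.85,
        ("inulin", "S1P"): 0.85,
    }
    teer_growth = {
        # terminally differentiated podocytes barely proliferate; endothelial
        # monolayers grow confluent; co-culture plateaus slightly higher
        "podocyte_only": TeerGrowth(teer_max=20.0),
        "endothelial_only": TeerGrowth(teer_max=60.0),
        "coculture": TeerGrowth(teer_max=70.0),
    }
    return TrueParams(
        resistance_apical=channel_resistance(presets.APICAL_CHANNEL, presets.WATER).value,
        resistance_basal=channel_resistance(presets.BASAL_CHANNEL, presets.WATER).value,
        permeability_k=permeability(presets.MEMBRANE),
        compliance_c1=c1,
        compliance_c2=c2,
        sieving=MappingProxyType(sieving),
        teer_growth=MappingProxyType(teer_growth),
    )


def default_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    return SyntheticScenario(seed=seed, **overrides)


# --------------------------------------------------------------------------
# Generators
# --------------------------------------------------------------------------


def gen_flow_recordings(
    scenario: SyntheticScenario,
    channel: str = "apical",
    pressures_mbar: Optional[Sequence[float]] = None,
    duration_s: float = 60.0,
    sample_rate: float = 10.0,
) -> pd.DataFrame:
    """Flow-meter recordings over a pressure staircase (default 0-150 mbar in
    15 mbar steps, 60 s per level). Columns: time_s, pressure_mbar,
    flow_ul_min. At zero noise each level reads exactly P/R_true."""
    if channel not in ("apical", "basal"):
        raise DomainError(f"unknown channel {channel!r}")
    r_true = (
        scenario.true_params.resistance_apical
        if channel == "apical"
        else scenario.true_params.resistance_basal
    )
    if pressures_mbar is None:
        pressures_mbar = np.arange(0.0, 151.0, 15.0)
    pressures_mbar = np.asarray(pressures_mbar, dtype=float)
    rng = scenario.rng("flow", 0 if channel == "apical" else 1)
    n_per = int(round(duration_s * sample_rate))
    fullscale = m3_s_to_ul_min(mbar_to_pa(float(pressures_mbar.max())) / r_true)
    sd = scenario.noise.flow_sd_frac_fullscale * fullscale

    frames = []
    t0 = 0.0
    for p in pressures_mbar:
        q_true = m3_s_to_ul_min(mbar_to_pa(p) / r_true)
        t = t0 + np.arange(n_per) / sample_rate
        q = q_true + (rng.normal(0.0, sd, n_per) if sd > 0 else 0.0)
        frames.append(
            pd.DataFrame(
                {"time_s": t, "pressure_mbar": p, "flow_ul_min": q}
            )
        )
        t0 += duration_s
    return pd.concat(frames, ignore_index=True)


def gen_deflection_sweep(
    scenario: SyntheticScenario,
    pressures_mbar: Optional[Sequence[float]] = None,
) -> list[DeflectionRecord]:
    """Focal-distance deflection sweep, default 0-315 mbar in 15 mbar steps
    (22 records). Deflection follows a(P) = c1 P^c2 plus focal noise,
    clamped at 0 (a focal reading cannot move behind the rest position)."""
    if pressures_mbar is None:
        pressures_mbar = np.arange(0.0, 316.0, 15.0)
    pressures_mbar = np.asarray(pressures_mbar, dtype=float)
    tp = scenario.true_params
    rng = scenario.rng("deflection")
    sd_mm = scenario.noise.focal_sd_um / 1000.0
    records = []
    for p in pressures_mbar:
        a = tp.compliance_c1 * p**tp.compliance_c2
        if sd_mm > 0:
            a += rng.normal(0.0, sd_mm)
        records.append(DeflectionRecord(float(p), max(a, 0.0)))
    return records


def _coverage(days: np.ndarray, g: TeerGrowth) -> np.ndarray:
    # logistic in time, shifted/rescaled so coverage(0) = 0 exactly
    s = 1.0 / (1.0 + np.exp(-g.rate * (days - g.midpoint_day)))
    s0 = 1.0 / (1.0 + np.exp(g.rate * g.midpoint_day))
    return (s - s0) / (1.0 - s0)


def gen_teer_timecourse(
    scenario: SyntheticScenario,
    condition: str,
    days: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Daily TEER measurements for one culture condition.

    Columns: day, condition, r_meas_ohm, r_blank_ohm, m_area_cm2. The
    noiseless final-day ordering is coculture > endothelial_only >
    podocyte_only by construction of the default plateaus."""
    tp = scenario.true_params
    if condition not in tp.teer_growth:
        raise DomainError(
            f"unknown condition {condition!r}; known: {sorted(tp.teer_growth)}"
        )
    if days is None:
        days = np.arange(0.0, 8.0)
    days = np.asarray(days, dtype=float)
    g = tp.teer_growth[condition]
    idx = sorted(tp.teer_growth).index(condition)
    rng = scenario.rng("teer", idx)
    teer_true = g.teer_max * _coverage(days, g)
    r_meas = tp.r_blank_ohm + teer_true / tp.m_area_cm2
    if scenario.noise.ohm_sd > 0:
        r_meas = r_meas + rng.normal(0.0, scenario.noise.ohm_sd, len(days))
    return pd.DataFrame(
        {
            "day": days,
            "condition": condition,
            "r_meas_ohm": r_meas,
            "r_blank_ohm": tp.r_blank_ohm,
            "m_area_cm2": tp.m_area_cm2,
        }
    )


def gen_filtration_readouts(
    scenario: SyntheticScenario,
    conditions: Sequence[str] = ("blank", "control", "S1P"),
    solutes: Sequence[str] = ("albumin", "inulin"),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Paired apical/basal outflow readouts (the assays CSV dialect plus a
    replicate column). Apical concentration = sieving x basal feed, with
    multiplicative log-normal noise of the configured CV; the basal outflow
    reads the feed concentration (2 mg/mL albumin, 0.1 mg/mL inulin)."""
    tp = scenario.true_params
    cv = scenario.noise.conc_cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    rng = scenario.rng("filtration")
    rows = []
    for solute in solutes:
        feed = tp.basal_feed_mg_ml.get(solute)
        if feed is None:
            raise DomainError(f"no basal feed concentration for solute {solute!r}")
        for condition in conditions:
            key = (solute, condition)
            if key not in tp.sieving:
                raise DomainError(f"no sieving coefficient for {key!r}")
            for rep in range(n_replicates):
                noise = np.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                rows.append(
                    {
                        "solute": solute,
                        "condition": condition,
                        "replicate": rep,
                        "conc_apical": tp.sieving[key] * feed * noise,
                        "apical_volume_ul": tp.apical_volume_ul,
                        "conc_basal": feed,
                    }
                )
    return pd.DataFrame(rows, columns=READOUT_COLUMNS[:2] + ["replicate"] + READOUT_COLUMNS[2:])


# --------------------------------------------------------------------------
# Fixture materialization
# --------------------------------------------------------------------------


def write_deflection_csv(records: Sequence[DeflectionRecord], path: str | Path) -> Path:
    """Write the mechanics CSV dialect: pressure_mbar, deflection_um."""
    path = Path(path)
    pd.DataFrame(
        {
            "pressure_mbar": [r.applied_pressure for r in records],
            "deflection_um": [r.deflection_a * 1000.0 for r in records],
        }
    ).to_csv(path, index=False)
    return path


def materialize_fixtures(scenario: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Write a full demo dataset tree consumable by the other modules."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for channel in ("apical", "basal"):
        p = outdir / f"flow_recordings_{channel}.csv"
        gen_flow_recordings(scenario, channel).to_csv(p, index=False)
        written[f"flow_recordings_{channel}"] = p
    p = outdir / "deflection_sweep.csv"
    write_deflection_csv(gen_deflection_sweep(scenario), p)
    written["deflection_sweep"] = p
    for condition in sorted(scenario.true_params.teer_growth):
        p = outdir / f"teer_{condition}.csv"
        gen_teer_timecourse(scenario, condition).to_csv(p, index=False)
        written[f"teer_{condition}"] = p
    p = outdir / "filtration_readouts.csv"
    gen_filtration_readouts(scenario).to_csv(p, index=False)
    written["filtration_readouts"] = p
    return written
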