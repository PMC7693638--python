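"""Barrier-function assay analytics.

TEER (trans-endothelial/epithelial electrical resistance) by the Ohm's-law
method: the blank-membrane resistance is subtracted from the measured
resistance and the remainder scaled by membrane area,

    TEER = (R_meas - R_blank) * M_area        [Ohm cm^2].

Solute filtration across the barrier follows the renal-clearance form: the
volume of basal-side feed cleared into the apical (urinary) compartment,

    Filtration = [A] * AV / [B]

with [A], [B] the apical/basal outflow concentrations and AV the collected
apical volume. Filtration on a cell-covered membrane is normalized to the
blank-membrane filtration of the same solute, giving a dimensionless barrier
index (1 = no barrier beyond the membrane, 0 = perfect retention).

Group-comparison statistics are deliberately not implemented; outputs are
tidy tables for any stats environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from .errors import ConfigurationError, DomainError, PairingError

__all__ = [
    "TEERRecord",
    "AssayReadout",
    "CalibrationCurve",
    "teer",
    "filtration",
    "normalized_filtration",
    "signal_to_concentration",
    "batch_assay",
    "read_readouts",
    "write_results",
]

#: Canonical readout-table columns (CSV dialect).
READOUT_COLUMNS = ["solute", "condition", "conc_apical", "apical_volume_ul", "conc_basal"]
RESULT_COLUMNS = ["solute", "condition", "filtration_ul", "normalized_filtration"]


@dataclass(frozen=True)
class TEERRecord:
    """One volt-ohm-meter measurement. ``m_area`` (cm^2) has no default:
    insert formats differ, so the area must be stated explicitly."""

    r_meas: float  # Ohm, with cells
    r_blank: float  # Ohm, membrane without cells
    m_area: float  # cm^2

    def __post_init__(self) -> None:
        if self.r_meas < 0 or self.r_blank < 0:
            raise DomainError("resistances must be >= 0")
        if self.m_area <= 0:
            raise DomainError("m_area must be > 0")


@dataclass(frozen=True)
class AssayReadout:
    """Paired apical/basal outflow readout for one solute and condition."""

    solute_label: str  # albumin, inulin, ...
    conc_apical: float  # mass/volume, apical outlet
    apical_volume: float  # collected apical volume (units carried to output)
    conc_basal: float  # mass/volume, basal outlet
    condition_label: str  # blank, cells, S1P, ...

    def __post_init__(self) -> None:
        if self.conc_apical < 0 or self.conc_basal < 0:
            raise DomainError("concentrations must be >= 0")
        if self.apical_volume <= 0:
            raise DomainError("apical_volume must be > 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear signal -> concentration map with blank subtraction
    (absorbance at 280 nm for albumin; fluorescence for FITC-inulin)."""

    mode: Literal["absorbance_280nm", "fluorescence"]
    slope: float  # signal per concentration unit
    intercept: float = 0.0
    blank_signal: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ConfigurationError("calibration slope must be > 0")


def teer(record: TEERRecord) -> float:
    """TEER in Ohm cm^2. A negative cell-layer resistance (sample below
    blank) is a common measurement artefact: it is returned as-is with a
    quality warning rather than raised, so batch runs do not crash."""
    r_cells = record.r_meas - record.r_blank
    if r_cells < 0:
        warnings.warn(
            f"R_meas ({record.r_meas}) below R_blank ({record.r_blank}): "
            "negative cell-layer resistance",
            stacklevel=2,
        )
    return r_cells * record.m_area


def filtration(readout: AssayReadout) -> float:
    """Cleared volume [A]*AV/[B], in the units of ``apical_volume``."""
    if readout.conc_basal <= 0:
        raise DomainError("conc_basal must be > 0 for a computable filtration")
    return readout.conc_apical * readout.apical_volume / readout.conc_basal


def normalized_filtration(f_cells: float, f_blank: float) -> float:
    """Filtration with cells relative to the blank membrane (dimensionless)."""
    if f_blank <= 0:
        raise DomainError("f_blank must be > 0")
    return f_cells / f_blank


def signal_to_concentration(signal: float, curve: CalibrationCurve) -> float:
    """Invert the linear calibration; negative results clamp to 0 with a
    warning (readings below blank are noise, not negative mass)."""
    conc = (signal - curve.blank_signal - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"signal {signal} below blank: concentration clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return conc


def batch_assay(readouts: pd.DataFrame, blank_label: str = "blank") -> pd.DataFrame:
    """Per-condition, per-solute normalized filtration table.

    Input columns: ``solute, condition, conc_apical, apical_volume_ul,
    conc_basal`` (replicates as repeated rows). Filtration is computed
    rowwise, averaged per (solute, condition), and normalized by the
    same-solute blank mean, so blank rows are exactly 1.0. Rows are ordered
    by (solute, condition). An empty table yields an empty result; a solute
    without a blank raises :class:`PairingError` naming it.
    """
    missing = [c for c in READOUT_COLUMNS if c not in readouts.columns]
    if missing:
        raise DomainError(f"readout table missing columns: {missing}")
    if len(readouts) == 0:
        return pd.DataFrame(columns=RESULT_COLUMNS)

    df = readouts.copy()
    if (df["conc_basal"] <= 0).any():
        raise DomainError("conc_basal must be > 0 for a computable filtration")
    if (df["apical_volume_ul"] <= 0).any():
        raise DomainError("apical_volume_ul must be > 0")
    df["filtration_ul"] = df["conc_apical"] * df["apical_volume_ul"] / df["conc_basal"]

    means = (
        df.groupby(["solute", "condition"], sort=True)["filtration_ul"]
        .mean()
        .reset_index()
    )
    blanks = means[means["condition"] == blank_label].set_index("solute")[
        "filtration_ul"
    ]
    for solute in means["solute"].unique():
        if solute not in blanks.index:
            raise PairingError(
                f"no blank ({blank_label!r}) readout for solute {solute!r}"
            )
        if blanks[solute] <= 0:
            raise DomainError(f"blank filtration for {solute!r} is not > 0")
    means["normalized_filtration"] = means.apply(
        lambda row: row["filtration_ul"] / blanks[row["solute"]], axis=1
    )
    return means[RESULT_COLUMNS].sort_values(["solute", "condition"]).reset_index(
        drop=True
    )


def read_readouts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in READOUT_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"readout CSV {path} missing columns: {missing}")
    return df


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    results.to_csv(path, index=False)
    return path
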