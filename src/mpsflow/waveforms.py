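"""Pneumatic pump pressure programs.

Programs are idealized command waveforms for the chip's pressure controllers:
a constant hold (e.g. the basal 80 mbar of the filtration protocol) or a
breathing-cycle sinusoid (e.g. 345 mbar amplitude at 0.33 Hz = 20
breaths/min for the alveolar stretch protocol). Pump actuation dynamics are
not modeled -- the realized pressure trace of a real pump differs from the
command -- because no transfer function is available for the hardware.

Exported CSV uses the dialect ``time_s,pressure_mbar`` with shortest-repr
float formatting, so export -> import -> export is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .errors import DomainError

__all__ = [
    "PumpProgram",
    "sine_program",
    "constant_program",
    "breathing_protocol",
    "gfb_protocol",
    "export_program",
    "import_program",
]

Channel = Literal["apical", "basal"]


@dataclass(frozen=True)
class PumpProgram:
    """Time-stamped pressure commands for one channel.

    ``sample_rate`` is descriptive metadata (not serialized) and is excluded
    from equality; two programs are equal when channel, times and pressures
    match exactly.
    """

    channel_label: Channel
    times: np.ndarray  # s, strictly increasing
    pressures: np.ndarray  # mbar, >= 0
    sample_rate: float = field(compare=False, default=10.0)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.pressures):
            raise DomainError("times and pressures must be paired")
        if len(self.times) == 0:
            raise DomainError("empty program")
        if not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.pressures < 0):
            raise DomainError("pressures must be >= 0 (pumps cannot pull vacuum)")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PumpProgram):
            return NotImplemented
        return (
            self.channel_label == other.channel_label
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.pressures, other.pressures)
        )


def _time_grid(duration: float, sample_rate: float) -> np.ndarray:
    if duration <= 0:
        raise DomainError("duration must be > 0")
    if sample_rate <= 0:
        raise DomainError("sample_rate must be > 0")
    n = int(round(duration * sample_rate))
    if n < 1:
        raise DomainError("duration * sample_rate must be >= 1")
    return np.arange(n + 1) / sample_rate  # inclusive endpoint


def sine_program(
    amplitude: float,
    frequency: float,
    offset: float,
    duration: float,
    sample_rate: float = 10.0,
    channel: Channel = "apical",
    clip: bool = False,
) -> PumpProgram:
    """Sinusoidal command p(t) = offset + amplitude*sin(2 pi f t), sampled on
    a regular inclusive grid.

    The commanded pressure must stay non-negative: require
    ``offset >= amplitude``, or pass ``clip=True`` to clamp troughs at 0.
    """
    if amplitude < 0:
        raise DomainError("amplitude must be >= 0")
    if frequency <= 0:
        raise DomainError("frequency must be > 0")
    if offset < amplitude and not clip:
        raise DomainError(
            "offset < amplitude would command negative pressure; "
            "raise the offset or enable clip"
        )
    t = _time_grid(duration, sample_rate)
    p = offset + amplitude * np.sin(2.0 * np.pi * frequency * t)
    if clip:
        p = np.maximum(p, 0.0)
    return PumpProgram(channel, t, p, sample_rate)


def constant_program(
    pressure: float,
    duration: float,
    sample_rate: float = 10.0,
    channel: Channel = "basal",
) -> PumpProgram:
    """Constant hold at ``pressure`` mbar."""
    if pressure < 0:
        raise DomainError("pressure must be >= 0")
    t = _time_grid(duration, sample_rate)
    return PumpProgram(channel, t, np.full_like(t, float(pressure)), sample_rate)


def breathing_protocol(
    duration: float = 60.0, sample_rate: float = 10.0
) -> PumpProgram:
    """Apical breathing-cycle protocol: 345 mbar amplitude at 20 breaths/min
    (0.33 Hz). The baseline is not specified by the protocol source; the
    offset is set to the amplitude so the trough just touches 0 mbar."""
    from .units import bpm_to_hz

    return sine_program(
        amplitude=345.0,
        frequency=bpm_to_hz(20.0),
        offset=345.0,
        duration=duration,
        sample_rate=sample_rate,
        channel="apical",
    )


def gfb_protocol(
    duration: float = 3600.0, sample_rate: float = 10.0
) -> tuple[PumpProgram, PumpProgram]:
    """Glomerular filtration protocol: constant 20 mbar apical (~15 mmHg) and
    80 mbar basal (~60 mmHg) for one hour."""
    return (
        constant_program(20.0, duration, sample_rate, channel="apical"),
        constant_program(80.0, duration, sample_rate, channel="basal"),
    )


def export_program(program: PumpProgram, path: str | Path) -> Path:
    """Write ``time_s,pressure_mbar`` CSV (one file per channel)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "pressure_mbar"])
        for t, p in zip(program.times, program.pressures):
            writer.writerow([repr(float(t)), repr(float(p))])
    return path


def import_program(path: str | Path, channel: Channel) -> PumpProgram:
    """Read a program CSV written by :func:`export_program`. The sample rate
    is inferred from the first time step."""
    path = Path(path)
    times: list[float] = []
    pressures: list[float] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["time_s", "pressure_mbar"]:
            raise DomainError(f"unexpected program header {header!r} in {path}")
        for row in reader:
            times.append(float(row[0]))
            pressures.append(float(row[1]))
    t = np.array(times)
    p = np.array(pressures)
    rate = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
    return PumpProgram(channel, t, p, rate)
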