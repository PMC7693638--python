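"""Unit conversions used at the package boundaries.

All internal computation is in SI (Pa, m, s, m^3/s). Interfaces accept the
units used at the bench: mbar on pressure controllers, mmHg for physiology,
uL/min on flow meters, breaths/min for respiratory rates.
"""

from .errors import DomainError

PA_PER_MBAR = 100.0
PA_PER_MMHG = 133.322
#: 1 mbar in mmHg (= 100/133.322 Pa ratio).
MMHG_PER_MBAR = 0.7500617
#: 1 m^3/s expressed in uL/min.
UL_MIN_PER_M3_S = 6.0e10


def mbar_to_pa(p_mbar: float) -> float:
    return p_mbar * PA_PER_MBAR


def pa_to_mbar(p_pa: float) -> float:
    return p_pa / PA_PER_MBAR


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * PA_PER_MMHG


def mbar_to_mmhg(p_mbar: float) -> float:
    """Convert a gauge pressure from mbar to mmHg.

    The devices' pressure controllers are programmed in mbar while the
    physiological literature quotes capillary pressures in mmHg (e.g. the
    glomerular trans-capillary pressure of ~60 mmHg is commanded as 80 mbar).
    """
    if p_mbar < 0:
        raise DomainError("p_mbar must be >= 0")
    return p_mbar * MMHG_PER_MBAR


def bpm_to_hz(breaths_per_minute: float) -> float:
    """Convert a breathing rate (breaths/min) to a pump drive frequency (Hz)."""
    if breaths_per_minute <= 0:
        raise DomainError("breaths_per_minute must be > 0")
    return breaths_per_minute / 60.0


def hz_to_bpm(frequency_hz: float) -> float:
    if frequency_hz <= 0:
        raise DomainError("frequency_hz must be > 0")
    return frequency_hz * 60.0


def ul_min_to_m3_s(q_ul_min: float) -> float:
    return q_ul_min / UL_MIN_PER_M3_S


def m3_s_to_ul_min(q_m3_s: float) -> float:
    return q_m3_s * UL_MIN_PER_M3_S
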