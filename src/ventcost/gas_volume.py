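"""BTPS ↔ STPD gas-volume conversion.

Expired-air volumes are measured at body temperature, ambient pressure,
saturated (BTPS); physiological comparisons use standard temperature and
pressure, dry (STPD). The conversion is the product of a temperature ratio
and a pressure ratio::

    STPD = BTPS * 273 / (273 + Btemp) * PB / Atm

with Btemp the body temperature (°C), PB the barometric pressure (mmHg) and
Atm standard atmospheric pressure (mmHg). The default instance (Btemp 37,
PB 635, Atm 760) gives a factor of 0.73580. A conventional saturated
water-vapor correction (PB − 47 mmHg at 37 °C) can be switched on via
``subtract_water_vapor``; it is off by default because the model's source
data were converted without it.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exceptions import DomainError

__all__ = ["VolumeConversionParams", "btps_to_stpd", "conversion_factor"]

_SVP_37C_MMHG = 47.0  # saturated water-vapor pressure at 37 °C


@dataclasses.dataclass(frozen=True)
class VolumeConversionParams:
    """Site conditions for the conversion; pressures in mmHg, temperature in °C."""

    btemp: float = 37.0
    pb: float = 635.0
    atm: float = 760.0
    subtract_water_vapor: bool = False

    def __post_init__(self) -> None:
        if self.btemp <= -273.0:
            raise DomainError("btemp must exceed absolute zero (−273 °C)")
        if self.pb <= 0 or self.atm <= 0:
            raise DomainError("pressures must be positive")


def conversion_factor(params: VolumeConversionParams | None = None) -> float:
    """The multiplicative BTPS→STPD factor for the given conditions."""
    p = params or VolumeConversionParams()
    pb = p.pb - _SVP_37C_MMHG if p.subtract_water_vapor else p.pb
    if pb <= 0:
        raise DomainError("water-vapor correction leaves non-positive pressure")
    return 273.0 / (273.0 + p.btemp) * pb / p.atm


def btps_to_stpd(volume, params: VolumeConversionParams | None = None):
    """Convert a volume (or volume rate) from BTPS to STPD conditions.

    Linear and order-preserving in `volume`; negative volumes are rejected.
    Accepts scalars or arrays.
    """
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise DomainError("volume must be non-negative")
    out = v * conversion_factor(params)
    return float(out) if out.ndim == 0 else out
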