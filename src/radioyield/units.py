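"""Centralized unit conversions.

Canonical internal units throughout the package: energies in MeV, mass
densities in g/cm^3, lengths in cm internally (interfaces accept and
report mm and um), times in hours, activities in MBq, beam currents in uA.
"""

from __future__ import annotations

#: Multiplicative factors converting a duration in the given unit to hours.
HOURS_PER_UNIT: dict[str, float] = {
    "ms": 1.0 / 3.6e6,
    "s": 1.0 / 3600.0,
    "min": 1.0 / 60.0,
    "h": 1.0,
    "d": 24.0,
}

CM_PER_MM = 0.1
CM_PER_UM = 1e-4
UM_PER_CM = 1e4
MM_PER_CM = 10.0

#: 1 millibarn in cm^2.
CM2_PER_MB = 1e-27

#: Protons per second carried by a 1 uA beam of singly charged particles
#: is ``1e-6 / elementary_charge``; the charge itself lives in
#: :mod:`radioyield.constants`.
AMPERE_PER_UA = 1e-6

BQ_PER_MBQ = 1e6


def hours(value: float, unit: str) -> float:
    """Convert a duration ``value`` expressed in ``unit`` to hours.

    ``unit`` must be one of ``ms``, ``s``, ``min``, ``h``, ``d``.
    """
    try:
        return value * HOURS_PER_UNIT[unit]
    except KeyError:
        raise ValueError(
            f"unknown duration unit {unit!r}; expected one of {sorted(HOURS_PER_UNIT)}"
        ) from None


def cm_from_mm(value_mm: float) -> float:
    return value_mm * CM_PER_MM


def um_from_cm(value_cm: float) -> float:
    return value_cm * UM_PER_CM
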