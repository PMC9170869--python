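"""Beam specification: energy, current and irradiation time."""

from __future__ import annotations

from dataclasses import dataclass

#: Validity window of the stopping-power model, MeV.
ENERGY_WINDOW = (1.0, 30.0)


@dataclass(frozen=True)
class BeamSpec:
    energy: float  # MeV
    current: float  # uA
    irradiation_time: float  # h

    def __post_init__(self) -> None:
        if not self.energy > 0 or not self.current > 0 or not self.irradiation_time > 0:
            raise ValueError("beam energy, current and irradiation time must be positive")
        lo, hi = ENERGY_WINDOW
        if not lo <= self.energy <= hi:
            raise ValueError(
                f"beam energy {self.energy} MeV outside the {lo}-{hi} MeV "
                "validity window of the stopping model"
            )

    @property
    def charge_uah(self) -> float:
        """Integrated beam charge in uA h."""
        return self.current * self.irradiation_time
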