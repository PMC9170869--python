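"""Physical constants for the Bethe stopping-power model (CODATA 2018)."""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Read-only constants entering the Bethe formula.

    Attributes
    ----------
    coulomb_constant : float
        k0 in N m^2 C^-2.
    elementary_charge : float
        e in C.
    electron_rest_mass_energy : float
        m_e c^2 in MeV.
    proton_rest_mass_energy : float
        m_p c^2 in MeV; used to obtain beta from the proton kinetic energy.
    proton_charge_number : int
        z of the projectile (1 for protons).
    speed_of_light : float
        c in m/s.
    avogadro : float
        N_A in mol^-1.
    """

    coulomb_constant: float = 8.9875517923e9
    elementary_charge: float = 1.602176634e-19
    electron_rest_mass_energy: float = 0.51099895
    proton_rest_mass_energy: float = 938.27208816
    proton_charge_number: int = 1
    speed_of_light: float = 299792458.0
    avogadro: float = 6.02214076e23

    @property
    def classical_electron_radius_cm(self) -> float:
        """r_e = k0 e^2 / (m_e c^2), in cm."""
        mec2_joule = self.electron_rest_mass_energy * 1e6 * self.elementary_charge
        r_m = self.coulomb_constant * self.elementary_charge**2 / mec2_joule
        return r_m * 100.0

    @property
    def bethe_coefficient(self) -> float:
        """K = 4 pi N_A r_e^2 m_e c^2 in MeV cm^2 / mol (~0.307075).

        Multiplied by the material's electrons-per-gram in mol/g and the
        kinematic factor, this yields the mass stopping power in MeV cm^2/g.
        """
        re = self.classical_electron_radius_cm
        return 4.0 * math.pi * self.avogadro * re**2 * self.electron_rest_mass_energy


CODATA = PhysicalConstants()
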