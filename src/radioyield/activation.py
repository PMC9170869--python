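"""Thick-target activation yield over the in-target energy window.

For a production channel with excitation function sigma(E), parent-atom
areal structure set by the target composition and isotopic abundance, and
a beam degraded from E_in to E_out across the layer, the end-of-bombardment
activity is

    A_EOB = (I / e) (1 - exp(-lambda t_irr)) * (N_A w f_a / M)
            * integral_{E_out}^{E_in} sigma(E) / (dE/d(rho x)) dE,

the standard activation equation with the saturation factor
(1 - exp(-lambda t)). The integral converts the depth integral of the
reaction density into an energy integral through the CSDA relation
dE/d(rho x) = mass stopping power.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beam import BeamSpec
from .materials import Material, tellurium_dioxide
from .nuclides import Nuclide, get_nuclide
from .stopping import STOPPED, StoppingModel
from .units import AMPERE_PER_UA, CM2_PER_MB


@dataclass(frozen=True)
class CrossSectionTable:
    """Tabulated excitation function sigma(E) for one production channel."""

    channel: str
    product: Nuclide
    energies: tuple[float, ...]  # MeV, strictly increasing
    sigma: tuple[float, ...]  # mb, non-negative
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", tuple(float(x) for x in self.energies))
        object.__setattr__(self, "sigma", tuple(float(x) for x in self.sigma))
        e = np.asarray(self.energies, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if e.size != s.size:
            raise ValueError(f"{self.channel}: energy and sigma grids differ in length")
        if e.size < 3:
            raise ValueError(f"{self.channel}: at least 3 grid points required")
        if np.any(np.diff(e) <= 0):
            raise ValueError(f"{self.channel}: energy grid must be strictly increasing")
        if np.any(s < 0):
            raise ValueError(f"{self.channel}: cross sections must be non-negative")

    def sigma_at(self, energy) -> np.ndarray:
        """Linear interpolation in mb; zero outside the grid (no extrapolation)."""
        e = np.asarray(self.energies)
        s = np.asarray(self.sigma)
        return np.interp(np.asarray(energy, dtype=float), e, s, left=0.0, right=0.0)

    @property
    def grid_span(self) -> tuple[float, float]:
        return (self.energies[0], self.energies[-1])

    def to_csv(self) -> str:
        buf = io.StringIO()
        pd.DataFrame({"energy_MeV": self.energies, "sigma_mb": self.sigma}).to_csv(
            buf, index=False
        )
        return buf.getvalue()

    @classmethod
    def from_csv(cls, source, sidecar=None) -> "CrossSectionTable":
        """Read ``energy_MeV,sigma_mb`` CSV plus a sidecar JSON with channel
        metadata (``channel``, ``product``, ``product_half_life_h``)."""
        frame = pd.read_csv(source)
        meta = {}
        if sidecar is not None:
            if hasattr(sidecar, "read"):
                meta = json.load(sidecar)
            elif str(sidecar).lstrip().startswith("{"):
                meta = json.loads(str(sidecar))
            else:
                with open(sidecar) as fh:
                    meta = json.load(fh)
        product_symbol = meta.get("product", "I-124")
        if "product_half_life_h" in meta:
            product = Nuclide(product_symbol, float(meta["product_half_life_h"]), "h")
        else:
            product = get_nuclide(product_symbol)
        return cls(
            channel=meta.get("channel", "unknown"),
            product=product,
            energies=tuple(frame["energy_MeV"].astype(float)),
            sigma=tuple(frame["sigma_mb"].astype(float)),
            source=meta.get("source", ""),
        )


@dataclass(frozen=True)
class TargetSpec:
    """Target layer plus the parent isotope the channel consumes."""

    material: Material
    thickness_mm: float
    parent_isotope: str  # e.g. "Te-124"
    parent_abundance: float  # isotopic fraction of the parent element
    parent_mass_fraction: float  # mass fraction of the parent element in the material
    parent_molar_mass: float  # g/mol of the parent element

    def __post_init__(self) -> None:
        if not 0 < self.parent_abundance <= 1:
            raise ValueError("parent abundance must be in (0, 1]")
        if not self.thickness_mm > 0:
            raise ValueError("target thickness must be positive")
        if self.parent_mass_fraction <= 0:
            raise ValueError(
                f"parent element of {self.parent_isotope} absent from material "
                f"{self.material.name}"
            )

    def with_thickness(self, thickness_mm: float) -> "TargetSpec":
        return TargetSpec(
            self.material,
            thickness_mm,
            self.parent_isotope,
            self.parent_abundance,
            self.parent_mass_fraction,
            self.parent_molar_mass,
        )

    @property
    def parent_atoms_per_gram(self) -> float:
        """N_A w f_a / M: parent atoms per gram of target material."""
        from .constants import CODATA

        return (
            CODATA.avogadro
            * self.parent_mass_fraction
            * self.parent_abundance
            / self.parent_molar_mass
        )


def teo2_target(
    thickness_mm: float, abundance: float = 0.0474, density: float = 5.65
) -> TargetSpec:
    """TeO2 target for the Te-124(p,n)I-124 channel.

    ``abundance`` defaults to the natural Te-124 isotopic abundance
    (4.74%); enriched targets are commonly ~99.5%.
    """
    material = tellurium_dioxide(density)
    return TargetSpec(
        material=material,
        thickness_mm=thickness_mm,
        parent_isotope="Te-124",
        parent_abundance=abundance,
        parent_mass_fraction=material.mass_fraction("Te"),
        parent_molar_mass=123.9028,  # Te-124 isotopic mass
    )


@dataclass(frozen=True)
class YieldResult:
    eob_activity: float  # MBq
    saturation_activity: float  # MBq
    yield_per_uah: float  # MBq / (uA h)
    energy_window: tuple[float, float]  # MeV in target
    fully_stopped: bool
    window_clipped: bool = False  # window extended beyond the sigma grid
    empty_window: bool = False

    def __post_init__(self) -> None:
        if self.eob_activity > self.saturation_activity * (1 + 1e-12):
            raise ValueError("EOB activity cannot exceed saturation activity")
        if self.yield_per_uah < 0:
            raise ValueError("yield must be non-negative")


def yield_per_uah(eob_activity: float, current: float, irradiation_time: float) -> float:
    """Normalize an EOB activity to MBq per uA h of integrated charge."""
    if current <= 0 or irradiation_time <= 0:
        raise ValueError("current and irradiation time must be positive")
    return eob_activity / (current * irradiation_time)


def thick_target_eob_activity(
    xs: CrossSectionTable,
    target: TargetSpec,
    beam: BeamSpec,
    stopping: StoppingModel,
    n_quadrature: int = 2000,
) -> YieldResult:
    """EOB activity from integrating sigma(E) across the in-target window.

    The energy window comes from slab degradation of the beam across the
    target thickness; sigma is linearly interpolated on its grid and zero
    outside (``window_clipped`` flags windows reaching past the grid).
    The quadrature is trapezoid on a dense energy grid joined with the
    sigma grid nodes, so the piecewise-linear integrand is captured
    exactly up to the stopping-power curvature.
    """
    window = stopping.energy_window_in_target(
        target.material, target.thickness_mm, beam.energy
    )
    e_hi, e_lo = window.energy_in, window.energy_out
    grid_lo, grid_hi = xs.grid_span
    clipped = e_hi > grid_hi or e_lo < grid_lo
    a, b = max(e_lo, grid_lo), min(e_hi, grid_hi)
    if b <= a:
        return YieldResult(
            0.0, 0.0, 0.0, (e_hi, e_lo), window.fully_stopped,
            window_clipped=clipped, empty_window=True,
        )
    e = np.linspace(a, b, n_quadrature)
    nodes = np.asarray(xs.energies)
    e = np.unique(np.concatenate([e, nodes[(nodes > a) & (nodes < b)]]))
    integrand = (
        xs.sigma_at(e)
        * CM2_PER_MB
        / stopping.mass_stopping_power(target.material, e)
    )
    integral = float(np.trapezoid(integrand, e))  # cm^2 * g/cm^2 / ... -> g^-1 scale
    reactions_per_proton = target.parent_atoms_per_gram * integral
    protons_per_s = beam.current * AMPERE_PER_UA / stopping.constants.elementary_charge
    saturation_bq = protons_per_s * reactions_per_proton
    lam = xs.product.decay_constant  # h^-1
    saturation_factor = 1.0 - np.exp(-lam * beam.irradiation_time)
    eob_mbq = saturation_bq * saturation_factor / 1e6
    sat_mbq = saturation_bq / 1e6
    return YieldResult(
        eob_activity=eob_mbq,
        saturation_activity=sat_mbq,
        yield_per_uah=yield_per_uah(eob_mbq, beam.current, beam.irradiation_time),
        energy_window=(e_hi, e_lo),
        fully_stopped=window.fully_stopped,
        window_clipped=clipped,
    )


def sweep_production(
    xs: CrossSectionTable,
    target: TargetSpec,
    target_thicknesses_mm,
    foil: Material,
    foil_thicknesses_mm,
    beam: BeamSpec,
    stopping: StoppingModel,
) -> pd.DataFrame:
    """Yield table over a (foil thickness x target thickness) grid.

    Mirrors degrader/target optimization sweeps: for each foil thickness
    the beam is degraded from the nominal energy, then the activation
    integral is evaluated for each target thickness. Rows where the foil
    stops the beam are flagged and carry zero yield.
    """
    rows = []
    for t_foil in foil_thicknesses_mm:
        if t_foil < 0:
            raise ValueError("foil thickness must be >= 0")
        e_on_target = (
            beam.energy
            if t_foil == 0
            else stopping.energy_after_slab(foil, t_foil, beam.energy)
        )
        from .beam import ENERGY_WINDOW

        if e_on_target is not STOPPED and e_on_target < ENERGY_WINDOW[0]:
            # below the model validity floor: no usable beam on target
            e_on_target = STOPPED
        for t_target in target_thicknesses_mm:
            spec = target.with_thickness(t_target)
            if e_on_target is STOPPED:
                rows.append(
                    {
                        "foil_mm": t_foil,
                        "target_mm": t_target,
                        "energy_on_target_MeV": np.nan,
                        "eob_MBq": 0.0,
                        "yield_MBq_per_uAh": 0.0,
                        "stopped_in_foil": True,
                        "fully_stopped_in_target": False,
                    }
                )
                continue
            degraded_beam = BeamSpec(e_on_target, beam.current, beam.irradiation_time)
            result = thick_target_eob_activity(xs, spec, degraded_beam, stopping)
            rows.append(
                {
                    "foil_mm": t_foil,
                    "target_mm": t_target,
                    "energy_on_target_MeV": e_on_target,
                    "eob_MBq": result.eob_activity,
                    "yield_MBq_per_uAh": result.yield_per_uah,
                    "stopped_in_foil": False,
                    "fully_stopped_in_target": result.fully_stopped,
                }
            )
    return pd.DataFrame(rows)
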