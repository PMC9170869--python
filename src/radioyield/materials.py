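"""Materials: element mass fractions, density and derived electron structure.

A :class:`Material` is the medium of the stopping-power model. Its derived
quantities are the electron density (the ``n`` of the Bethe formula,
exposed per gram and per cm^3) and a compound mean excitation energy
obtained by Bragg additivity on ln I weighted by electron fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .constants import CODATA
from .elements import Element, get_element

_FRACTION_TOL = 1e-6


@dataclass(frozen=True)
class Material:
    name: str
    composition: tuple[tuple[Element, float], ...]  # (element, mass fraction)
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"material {self.name}: density must be positive")
        if not self.composition:
            raise ValueError(f"material {self.name}: empty composition")
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"material {self.name}: mass fractions sum to {total!r}, not 1"
            )

    @property
    def electrons_per_gram(self) -> float:
        """Sum_i w_i N_A Z_i / M_i, electrons per gram."""
        return sum(w * el.electrons_per_gram for el, w in self.composition)

    @property
    def electrons_per_mol_gram(self) -> float:
        """Effective <Z/A> in mol electrons per gram (electrons_per_gram / N_A)."""
        return self.electrons_per_gram / CODATA.avogadro

    @property
    def electron_density(self) -> float:
        """Electrons per cm^3 at the material density."""
        return self.electrons_per_gram * self.density

    @property
    def mean_excitation_energy(self) -> float:
        """Compound I in eV: Bragg additivity on ln I, electron-fraction weights."""
        num = 0.0
        den = 0.0
        for el, w in self.composition:
            ne = w * el.electrons_per_gram
            num += ne * math.log(el.mean_excitation_energy)
            den += ne
        return math.exp(num / den)

    def mass_fraction(self, symbol: str) -> float:
        """Mass fraction of element ``symbol`` (0 when absent)."""
        return sum(w for el, w in self.composition if el.symbol == symbol)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "density_g_cm3": self.density,
                "composition": {el.symbol: w for el, w in self.composition},
            },
            indent=2,
        )


def make_material(
    name: str, composition: list[tuple[str, float]], density: float
) -> Material:
    """Build a :class:`Material` from (element symbol, mass fraction) pairs.

    Fractions must lie in (0, 1] and sum to 1 within 1e-6; there is no
    silent renormalization of grossly unbalanced inputs, but the residual
    rounding within tolerance is spread proportionally so downstream
    invariants hold exactly.
    """
    if not composition:
        raise ValueError("composition must not be empty")
    for symbol, w in composition:
        if not 0 < w <= 1:
            raise ValueError(
                f"mass fraction for {symbol} must be in (0, 1], got {w}"
            )
    total = sum(w for _, w in composition)
    if abs(total - 1.0) > _FRACTION_TOL:
        raise ValueError(
            f"mass fractions sum to {total:.6g}; expected 1 within {_FRACTION_TOL}"
        )
    pairs = tuple((get_element(sym), w / total) for sym, w in composition)
    return Material(name, pairs, density)


def material_from_json(source) -> Material:
    """Load a material from the JSON interface written by ``Material.to_json``."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            doc = json.loads(text)
        else:
            with open(text) as fh:
                doc = json.load(fh)
    comp = [(sym, float(w)) for sym, w in doc["composition"].items()]
    return make_material(doc["name"], comp, float(doc["density_g_cm3"]))


# -- bundled materials -------------------------------------------------------

def tellurium_dioxide(density: float = 5.65) -> Material:
    """TeO2 glass; the default density is that of the vitreous phase."""
    m_te = get_element("Te").molar_mass
    m_o = get_element("O").molar_mass
    w_te = m_te / (m_te + 2 * m_o)
    return make_material("TeO2", [("Te", w_te), ("O", 1 - w_te)], density)


def aluminum(density: float = 2.7) -> Material:
    return make_material("Al", [("Al", 1.0)], density)


def molybdenum(density: float = 10.2) -> Material:
    return make_material("Mo", [("Mo", 1.0)], density)


def havar(density: float = 8.3) -> Material:
    """Havar degrader alloy.

    The standard nominal composition (Co 42.5, Cr 20.0, Fe 17.9, Ni 13.0,
    W 2.8, Mo 2.2, Mn 1.6 wt%) is assumed; foil vendors vary at the few
    tenths of a percent level, which is negligible for stopping.
    """
    return make_material(
        "Havar",
        [
            ("Co", 0.425),
            ("Cr", 0.200),
            ("Fe", 0.179),
            ("Ni", 0.130),
            ("W", 0.028),
            ("Mo", 0.022),
            ("Mn", 0.016),
        ],
        density,
    )


BUNDLED_MATERIALS = {
    "TeO2": tellurium_dioxide,
    "Al": aluminum,
    "Mo": molybdenum,
    "Havar": havar,
}
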