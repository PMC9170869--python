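"""Element data: atomic number, molar mass and mean excitation energy.

Mean excitation energies I follow the ICRU-49 recommended element values,
which govern the Bethe logarithm. The bundled list covers the elements
used by the degrader foils (Al, Mo, Havar alloy), tellurium-dioxide
targets and a few light elements for user-defined compounds.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    molar_mass: float  # g/mol
    mean_excitation_energy: float  # eV

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"element {self.symbol}: Z must be >= 1, got {self.Z}")
        if self.mean_excitation_energy <= 0:
            raise ValueError(
                f"element {self.symbol}: mean excitation energy must be positive"
            )

    @property
    def electrons_per_gram(self) -> float:
        """N_A Z / M, electrons per gram of the pure element."""
        from .constants import CODATA

        return CODATA.avogadro * self.Z / self.molar_mass


ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("H", 1, 1.008, 19.2),
        Element("C", 6, 12.011, 78.0),
        Element("N", 7, 14.007, 82.0),
        Element("O", 8, 15.999, 95.0),
        Element("Al", 13, 26.9815385, 166.0),
        Element("Si", 14, 28.085, 173.0),
        Element("Ti", 22, 47.867, 233.0),
        Element("Cr", 24, 51.9961, 257.0),
        Element("Mn", 25, 54.938044, 272.0),
        Element("Fe", 26, 55.845, 286.0),
        Element("Co", 27, 58.933194, 297.0),
        Element("Ni", 28, 58.6934, 311.0),
        Element("Cu", 29, 63.546, 322.0),
        Element("Mo", 42, 95.95, 424.0),
        Element("Te", 52, 127.60, 485.0),
        Element("W", 74, 183.84, 727.0),
        Element("Pt", 78, 195.084, 790.0),
    ]
}


def get_element(symbol: str) -> Element:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element {symbol!r}; bundled elements: {sorted(ELEMENTS)}"
        ) from None
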