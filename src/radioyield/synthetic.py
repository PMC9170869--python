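"""Synthetic inputs: calibrated toy excitation functions, random inventories.

The toy excitation function is a single Gaussian peak calibrated to the
two constraints the Te-124(p,n)I-124 channel is known to satisfy near its
maximum: sigma(14 MeV) ~ 300 mb and sigma(14)/sigma(18) ~ 3, with the
peak near 13 MeV. It is analytically tractable and deliberately NOT a
reproduction of the evaluated excitation-function shape; quantitative
claims made with it are limited to those anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .activation import CrossSectionTable
from .inventory import ActivityInventory
from .nuclides import Nuclide, get_nuclide


@dataclass(frozen=True)
class ToyExcitationFunction:
    """Gaussian sigma(E) = peak_sigma * exp(-(E - peak_energy)^2 / (2 width^2))."""

    peak_energy: float  # MeV
    peak_sigma: float  # mb
    width: float  # MeV (Gaussian sd)
    grid: tuple[float, ...]  # MeV

    def sigma(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        return self.peak_sigma * np.exp(
            -((e - self.peak_energy) ** 2) / (2.0 * self.width**2)
        )

    def table(self, product: Nuclide | None = None) -> CrossSectionTable:
        product = product or get_nuclide("I-124")
        return CrossSectionTable(
            channel="Te-124(p,n)I-124[toy]",
            product=product,
            energies=self.grid,
            sigma=tuple(self.sigma(np.asarray(self.grid))),
            source="synthetic Gaussian toy",
        )


def solve_toy_parameters(
    peak_energy: float = 13.0,
    anchor: tuple[float, float] = (14.0, 300.0),
    ratio_energy: float = 18.0,
    ratio: float = 3.0,
    grid_span: tuple[float, float] = (4.0, 20.0),
    grid_step: float = 0.1,
) -> ToyExcitationFunction:
    """Solve width and peak cross section from the two anchor constraints.

    sigma(E_a) = s_a and sigma(E_a)/sigma(E_r) = ratio give

        width^2 = ((E_r - E_p)^2 - (E_a - E_p)^2) / (2 ln ratio).
    """
    if not 10.0 < peak_energy < 16.0:
        raise ValueError(f"peak_energy must lie in (10, 16) MeV, got {peak_energy}")
    e_a, s_a = anchor
    num = (ratio_energy - peak_energy) ** 2 - (e_a - peak_energy) ** 2
    if num <= 0 or ratio <= 1:
        raise ValueError(
            "no Gaussian solution: the ratio point must lie farther from the "
            "peak than the anchor and the ratio must exceed 1"
        )
    width = math.sqrt(num / (2.0 * math.log(ratio)))
    peak_sigma = s_a * math.exp((e_a - peak_energy) ** 2 / (2.0 * width**2))
    n = int(round((grid_span[1] - grid_span[0]) / grid_step)) + 1
    grid = tuple(np.linspace(grid_span[0], grid_span[1], n))
    return ToyExcitationFunction(peak_energy, peak_sigma, width, grid)


def calibrated_toy_xs(peak_energy: float = 13.0) -> CrossSectionTable:
    """Calibrated toy excitation function on a 0.1 MeV grid over 4-20 MeV."""
    return solve_toy_parameters(peak_energy).table()


def random_inventory(
    n_nuclides: int,
    half_life_range_h: tuple[float, float] = (0.01, 2000.0),
    activity_range_mbq: tuple[float, float] = (0.1, 5000.0),
    seed: int = 0,
) -> ActivityInventory:
    """Random EOB-style inventory with log-uniform half-lives and activities.

    Emulates the structure of real post-irradiation inventories: half-lives
    spanning minutes to months and activities spanning orders of magnitude.
    Reproducible for a fixed seed; the seed is mandatory state, there is no
    hidden global generator.
    """
    if n_nuclides < 1:
        raise ValueError("n_nuclides must be >= 1")
    for lo, hi, what in [
        (*half_life_range_h, "half-life"),
        (*activity_range_mbq, "activity"),
    ]:
        if not 0 < lo < hi:
            raise ValueError(f"invalid {what} range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    half_lives = np.exp(
        rng.uniform(*np.log(half_life_range_h), size=n_nuclides)
    )
    activities = np.exp(rng.uniform(*np.log(activity_range_mbq), size=n_nuclides))
    rows = [
        (f"SYN-{i + 1}", float(half_lives[i]), "h", float(activities[i]))
        for i in range(n_nuclides)
    ]
    return ActivityInventory.from_rows(rows)
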