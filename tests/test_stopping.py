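"""Stopping power and range checks against independent brute-force oracles.

The oracles re-derive the Bethe expression from scipy.constants values and
integrate it with a fixed 1 keV trapezoid rule, independently of the
package's tabulated-PCHIP path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from radioyield import STOPPED, StoppingModel, molybdenum

from oracles import oracle_csda_range_um, oracle_mass_stopping


def test_mass_stopping_power_matches_formula_oracle(model, al, teo2, havar_foil):
    for material in (al, teo2, havar_foil):
        for energy in (5.0, 10.0, 18.0, 29.0):
            assert model.mass_stopping_power(material, energy) == pytest.approx(
                oracle_mass_stopping(material, energy), rel=1e-4
            )


def test_mass_stopping_power_is_density_independent(model, teo2):
    from radioyield import tellurium_dioxide

    dense = tellurium_dioxide(density=11.3)
    assert model.mass_stopping_power(teo2, 14.8) == pytest.approx(
        model.mass_stopping_power(dense, 14.8), rel=1e-12
    )
    # but the linear stopping power scales with density
    assert model.stopping_power(dense, 14.8) == pytest.approx(
        2 * model.stopping_power(teo2, 14.8), rel=1e-12
    )


def test_stopping_power_decreasing_and_range_increasing(model, al, teo2, havar_foil):
    energies = np.linspace(5.0, 30.0, 40)
    for material in (al, teo2, havar_foil, molybdenum()):
        s = model.mass_stopping_power(material, energies)
        assert np.all(np.diff(s) < 0)
        r = [model.csda_range(material, e) for e in energies]
        assert np.all(np.diff(r) > 0)


def test_energy_outside_validity_window_raises(model, teo2):
    with pytest.raises(ValueError, match="validity window"):
        model.mass_stopping_power(teo2, 0.05)
    with pytest.raises(ValueError, match="validity window"):
        model.csda_range(teo2, 40.0)


def test_csda_range_matches_brute_force_oracle(model, al):
    assert model.csda_range(al, 10.0) == pytest.approx(
        oracle_csda_range_um(al, 10.0), rel=1e-3
    )


def test_csda_range_vanishes_at_cutoff(model, teo2):
    assert model.csda_range(teo2, model.low_energy_cutoff) <= 3.0


def test_quadrature_oracle_equivalence_random_cases(model, al, teo2, havar_foil):
    """Tabulated-PCHIP ranges match the 1 keV brute-force integrator to 0.1%."""
    rng = np.random.default_rng(42)
    materials = [al, teo2, havar_foil]
    for _ in range(20):
        material = materials[rng.integers(len(materials))]
        energy = float(rng.uniform(2.0, 29.0))
        assert model.csda_range(material, energy) == pytest.approx(
            oracle_csda_range_um(material, energy), rel=1e-3
        )


def test_zero_thickness_slab_is_identity(model, teo2):
    assert model.energy_after_slab(teo2, 0.0, 14.8) == pytest.approx(14.8)


def test_thick_target_stops_beam(model, teo2):
    assert model.energy_after_slab(teo2, 1.0, 14.8) is STOPPED


def test_negative_thickness_rejected(model, teo2):
    with pytest.raises(ValueError, match=">= 0"):
        model.energy_after_slab(teo2, -0.1, 14.8)


def test_slab_strictly_degrades(model, havar_foil):
    out = model.energy_after_slab(havar_foil, 0.05, 18.0)
    assert out is not STOPPED and out < 18.0


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    energy=st.floats(8.0, 28.0),
    split=st.floats(0.1, 0.9),
    total_fraction=st.floats(0.1, 0.8),
)
def test_slab_additivity(model, teo2, energy, split, total_fraction):
    """Two consecutive slabs equal one combined slab within 1e-3 MeV."""
    total_mm = total_fraction * model.csda_range(teo2, energy) / 1000.0
    a, b = split * total_mm, (1 - split) * total_mm
    step1 = model.energy_after_slab(teo2, a, energy)
    assert step1 is not STOPPED
    two_step = model.energy_after_slab(teo2, b, step1)
    one_step = model.energy_after_slab(teo2, total_mm, energy)
    assert two_step is not STOPPED and one_step is not STOPPED
    assert two_step == pytest.approx(one_step, abs=1e-3)


def test_range_inversion_consistency(model, teo2, havar_foil):
    """R(E_out) == R(E_in) - rho t within 0.1%."""
    for material, t_mm, e_in in [(teo2, 0.3, 14.8), (havar_foil, 0.2, 18.0)]:
        e_out = model.energy_after_slab(material, t_mm, e_in)
        lhs = model.csda_range(material, e_out)
        rhs = model.csda_range(material, e_in) - t_mm * 1000.0
        assert lhs == pytest.approx(rhs, rel=1e-3)


def test_energy_window_cases(model, teo2):
    w = model.energy_window_in_target(teo2, 0.0, 14.8)
    assert w == (14.8, 14.8, False)
    w = model.energy_window_in_target(teo2, 0.5, 14.8)
    assert not w.fully_stopped and model.low_energy_cutoff < w.energy_out < 14.8
    w = model.energy_window_in_target(teo2, 1.0, 14.8)
    assert w.fully_stopped and w.energy_out == model.low_energy_cutoff


class TestRangeDistribution:
    def test_deterministic_under_fixed_seed(self, model, teo2):
        d1 = model.simulate_range_distribution(teo2, 14.8, 2000, seed=7)
        d2 = model.simulate_range_distribution(teo2, 14.8, 2000, seed=7)
        assert np.array_equal(d1.weights, d2.weights)
        assert d1.mode == d2.mode

    def test_mode_near_csda_range(self, model, teo2):
        d = model.simulate_range_distribution(teo2, 14.8, 100_000, seed=1)
        r = model.csda_range(teo2, 14.8)
        sigma = model.bohr_range_straggling(teo2, 14.8)
        assert abs(d.mode - r) < 3 * sigma
        assert d.sd == pytest.approx(sigma, rel=0.05)

    def test_mode_stable_across_seeds(self, model, teo2):
        d1 = model.simulate_range_distribution(teo2, 14.8, 100_000, seed=1)
        d2 = model.simulate_range_distribution(teo2, 14.8, 100_000, seed=2)
        assert abs(d1.mode - d2.mode) < 3.0

    def test_small_samples_rejected(self, model, teo2):
        with pytest.raises(ValueError, match="n_protons"):
            model.simulate_range_distribution(teo2, 14.8, 50, seed=1)
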