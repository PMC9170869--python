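"""Activation-yield checks: analytic thin-target limit, a depth-slab
brute-force oracle, and the scaling properties of the activation equation."""

import numpy as np
import pytest

from radioyield import (
    BeamSpec,
    CrossSectionTable,
    Nuclide,
    STOPPED,
    StoppingModel,
    calibrated_toy_xs,
    havar,
    sweep_production,
    teo2_target,
    thick_target_eob_activity,
    yield_per_uah,
)

from oracles import E_CHARGE, slab_oracle_eob_mbq

@pytest.fixture(scope="module")
def flat_xs():
    """Constant sigma = 100 mb over a wide grid."""
    return CrossSectionTable(
        channel="flat",
        product=Nuclide("I-124", 4.2, "d"),
        energies=(1.0, 15.0, 30.0),
        sigma=(100.0, 100.0, 100.0),
    )


def test_thin_target_closed_form(model, flat_xs):
    """A slab thin enough that dE < 0.1 MeV matches A = (I/e)(1-e^-lt) n sigma."""
    target = teo2_target(0.005)  # 5 um
    beam = BeamSpec(14.8, 10.0, 1.5)
    res = thick_target_eob_activity(flat_xs, target, beam, model)
    assert res.energy_window[0] - res.energy_window[1] < 0.1
    n_areal = target.parent_atoms_per_gram * target.material.density * 0.0005  # cm^-2
    lam = flat_xs.product.decay_constant
    closed = (
        beam.current * 1e-6 / E_CHARGE
        * n_areal * 100e-27
        * (1 - np.exp(-lam * 1.5))
        / 1e6
    )
    assert res.eob_activity == pytest.approx(closed, rel=1e-3)


def test_matches_depth_slab_oracle(model, toy_xs):
    target = teo2_target(0.5)
    beam = BeamSpec(14.8, 10.0, 1.5)
    res = thick_target_eob_activity(toy_xs, target, beam, model)
    oracle = slab_oracle_eob_mbq(toy_xs, target, beam, model)
    assert res.eob_activity == pytest.approx(oracle, rel=5e-3)


def test_oracle_equivalence_random_synthetic_cases(model):
    """Energy-integral yield equals the depth-slab oracle on random cases."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        peak = float(rng.uniform(10.5, 15.5))
        xs = calibrated_toy_xs(peak_energy=peak)
        thickness = float(rng.uniform(0.1, 0.8))
        energy = float(rng.uniform(10.0, 18.0))
        target = teo2_target(thickness)
        beam = BeamSpec(energy, 10.0, 1.5)
        res = thick_target_eob_activity(xs, target, beam, model)
        oracle = slab_oracle_eob_mbq(xs, target, beam, model)
        assert res.eob_activity == pytest.approx(oracle, rel=5e-3)


def test_linearity_in_current(model, toy_xs):
    target = teo2_target(0.5)
    a1 = thick_target_eob_activity(toy_xs, target, BeamSpec(14.8, 10, 1.5), model)
    a2 = thick_target_eob_activity(toy_xs, target, BeamSpec(14.8, 20, 1.5), model)
    assert a2.eob_activity == pytest.approx(2 * a1.eob_activity, rel=1e-12)


def test_saturation_limit(model, toy_xs):
    """EOB activity saturates: 20 vs 40 product half-lives differ by <0.01%."""
    target = teo2_target(0.5)
    t_half = toy_xs.product.half_life_h
    a20 = thick_target_eob_activity(toy_xs, target, BeamSpec(14.8, 10, 20 * t_half), model)
    a40 = thick_target_eob_activity(toy_xs, target, BeamSpec(14.8, 10, 40 * t_half), model)
    assert a40.eob_activity == pytest.approx(a20.eob_activity, rel=1e-4)
    assert a20.eob_activity <= a20.saturation_activity
    assert a40.eob_activity == pytest.approx(a40.saturation_activity, rel=1e-6)


def test_abundance_scaling_is_exactly_linear(model, toy_xs):
    beam = BeamSpec(14.8, 10, 1.5)
    natural = thick_target_eob_activity(toy_xs, teo2_target(0.5, abundance=0.0474), beam, model)
    enriched = thick_target_eob_activity(toy_xs, teo2_target(0.5, abundance=0.995), beam, model)
    assert enriched.eob_activity == pytest.approx(
        natural.eob_activity * 0.995 / 0.0474, rel=1e-12
    )


def test_empty_window_flagged(model):
    """A window entirely outside the sigma grid yields zero with a flag."""
    xs = CrossSectionTable(
        channel="high-only",
        product=Nuclide("I-124", 4.2, "d"),
        energies=(25.0, 27.0, 29.0),
        sigma=(10.0, 10.0, 10.0),
    )
    res = thick_target_eob_activity(xs, teo2_target(0.1), BeamSpec(10.0, 10, 1.5), model)
    assert res.empty_window and res.eob_activity == 0.0


def test_invalid_xs_tables_rejected():
    p = Nuclide("I-124", 4.2, "d")
    with pytest.raises(ValueError, match="increasing"):
        CrossSectionTable("c", p, (1.0, 1.0, 2.0), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="non-negative"):
        CrossSectionTable("c", p, (1.0, 2.0, 3.0), (1.0, -1.0, 1.0))
    with pytest.raises(ValueError, match="3 grid points"):
        CrossSectionTable("c", p, (1.0, 2.0), (1.0, 1.0))


class TestYieldNormalization:
    def test_simulated_natural_15ua_yield(self):
        # 35.594 MBq over 15 uA x 1.5 h
        assert yield_per_uah(35.594, 15.0, 1.5) == pytest.approx(1.582, abs=5e-4)

    def test_simulated_natural_10ua_yield(self):
        assert yield_per_uah(23.199, 10.0, 1.5) == pytest.approx(1.547, abs=5e-4)

    def test_zero_activity(self):
        assert yield_per_uah(0.0, 10.0, 1.5) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            yield_per_uah(1.0, 0.0, 1.5)


class TestSweep:
    def test_optimal_foil_for_thin_target(self, model, toy_xs):
        """For a sub-0.5 mm target at 18 MeV the best Havar foil is 0.2-0.3 mm."""
        foils = list(np.round(np.arange(0.05, 0.525, 0.025), 3))
        table = sweep_production(
            toy_xs, teo2_target(0.3), [0.3], havar(), foils,
            BeamSpec(18.0, 10, 1.5), model,
        )
        best = table.loc[table["eob_MBq"].idxmax()]
        assert 0.2 <= best["foil_mm"] <= 0.3

    def test_zero_foil_equals_no_degrader(self, model, toy_xs):
        table = sweep_production(
            toy_xs, teo2_target(0.5), [0.5], havar(), [0.0],
            BeamSpec(14.8, 10, 1.5), model,
        )
        direct = thick_target_eob_activity(
            toy_xs, teo2_target(0.5), BeamSpec(14.8, 10, 1.5), model
        )
        assert table["eob_MBq"].iloc[0] == pytest.approx(direct.eob_activity, rel=1e-12)

    def test_current_doubling_doubles_every_cell(self, model, toy_xs):
        args = (toy_xs, teo2_target(0.3), [0.3, 0.5], havar(), [0.1, 0.2])
        t10 = sweep_production(*args, BeamSpec(18.0, 10, 1.5), model)
        t20 = sweep_production(*args, BeamSpec(18.0, 20, 1.5), model)
        assert np.allclose(t20["eob_MBq"], 2 * t10["eob_MBq"], rtol=1e-12)

    def test_beam_stopped_in_thick_foil_flagged(self, model, toy_xs):
        table = sweep_production(
            toy_xs, teo2_target(0.5), [0.5], havar(), [5.0],
            BeamSpec(18.0, 10, 1.5), model,
        )
        row = table.iloc[0]
        assert row["stopped_in_foil"] and row["eob_MBq"] == 0.0
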