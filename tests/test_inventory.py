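"""Decay bookkeeping, purity solver and the published-inventory fixtures."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radioyield import (
    ActivityInventory,
    Nuclide,
    decay_activity,
    load_fixture,
    purity_time,
    relative_difference,
)
from radioyield.synthetic import random_inventory

from oracles import scan_oracle_release_time


def test_decay_activity_examples():
    i124 = Nuclide("I-124", 4.2, "d")
    assert decay_activity(214.711, i124, 72.0) == pytest.approx(130.499, rel=0.015)
    assert decay_activity(100.0, Nuclide("X", 10.0, "h"), 10.0) == pytest.approx(50.0)
    assert decay_activity(5.0, i124, 0.0) == 5.0
    with pytest.raises(ValueError, match=">= 0"):
        decay_activity(5.0, i124, -1.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    a0=st.floats(0.01, 1e4),
    t_half=st.floats(0.01, 5000.0),
    dt1=st.floats(0.0, 500.0),
    dt2=st.floats(0.0, 500.0),
)
def test_decay_semigroup(a0, t_half, dt1, dt2):
    """Decaying by a then b equals decaying by a+b (relative 1e-12)."""
    n = Nuclide("X", t_half, "h")
    two = decay_activity(decay_activity(a0, n, dt1), n, dt2)
    one = decay_activity(a0, n, dt1 + dt2)
    assert two == pytest.approx(one, rel=1e-12)


def test_inventory_decay_and_totals():
    inv = load_fixture("natural_10uA")
    assert inv.total() == pytest.approx(8377.059, abs=0.01)
    decayed = inv.decay(72.0)
    assert decayed.reference_time == 72.0
    assert decayed.total() == pytest.approx(33.966, rel=0.01)
    assert inv.decay(0.0).total() == pytest.approx(inv.total(), rel=1e-12)
    with pytest.raises(ValueError):
        inv.decay(-1.0)


def test_total_strictly_decreases():
    inv = random_inventory(8, seed=3)
    totals = [inv.decay(t).total() for t in (0.0, 1.0, 10.0, 100.0)]
    assert all(b < a for a, b in zip(totals, totals[1:]))


def test_empty_inventory():
    inv = ActivityInventory()
    assert inv.decay(50.0).total() == 0.0


def test_activity_fractions():
    inv = load_fixture("natural_10uA", half_lives="evaluated").decay(72.0)
    assert inv.fraction("I-124") == pytest.approx(41.47, abs=1.0)
    solo = ActivityInventory.from_rows([("I-124", 4.2, "d", 12.0)])
    assert solo.fraction("I-124") == 100.0
    with pytest.raises(KeyError):
        inv.fraction("Xx-1")


def test_negligible_flagging():
    inv = ActivityInventory.from_rows(
        [("I-124", 4.2, "d", 10.0), ("I-122", 3.6, "min", 1.0)]
    )
    late = inv.decay(24.0)
    assert late.is_negligible("I-122") and not late.is_negligible("I-124")
    assert "I-122" in late.symbols  # retained, not dropped


def test_inventory_csv_round_trip():
    inv = load_fixture("natural_15uA")
    again = ActivityInventory.from_csv(io.StringIO(inv.to_csv()))
    assert again.symbols == inv.symbols
    for s in inv.symbols:
        assert again.activity(s) == pytest.approx(inv.activity(s), rel=1e-12)
        assert again.nuclide(s).half_life_h == pytest.approx(
            inv.nuclide(s).half_life_h, rel=1e-12
        )


class TestRelativeDifference:
    def test_published_rows(self):
        assert relative_difference(20.72, 33.30) == pytest.approx(60.71, abs=0.01)
        assert relative_difference(56.61, 50.32) == pytest.approx(11.11, abs=0.01)

    def test_identity_and_errors(self):
        assert relative_difference(5.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            relative_difference(0.0, 5.0)


class TestPurityTime:
    def test_natural_15ua_release(self):
        inv = load_fixture("natural_15uA", half_lives="evaluated")
        res = purity_time(inv, "I-123")
        assert res.found and abs(res.impurity_fraction - 0.0035) <= 1e-6
        assert res.release_time == pytest.approx(122.0, abs=4.0)
        assert res.product_activity == pytest.approx(15.318, rel=0.015)

    def test_enriched_15ua_release(self):
        inv = load_fixture("enriched_15uA", half_lives="evaluated")
        res = purity_time(inv, "I-123")
        assert res.release_time == pytest.approx(151.0, abs=4.0)
        assert res.product_activity == pytest.approx(117.327, rel=0.015)

    def test_no_impurity_is_already_pure(self):
        inv = ActivityInventory.from_rows(
            [("I-124", 4.2, "d", 10.0), ("I-123", 13.2, "h", 0.0)]
        )
        res = purity_time(inv, "I-123")
        assert res.already_pure and res.release_time == 0.5

    def test_no_crossing_reports_bounds(self):
        # impurity outlives the product: fraction grows, never crosses down
        inv = ActivityInventory.from_rows(
            [("PROD", 5.0, "h", 100.0), ("IMP", 5000.0, "h", 50.0)]
        )
        res = purity_time(inv, "IMP", product="PROD", bracket=(0.5, 200.0))
        assert not res.found
        assert res.min_fraction > 0.0035 and res.max_fraction <= 1.0

    def test_matches_scan_oracle_on_random_inventories(self):
        hits = 0
        for seed in range(12):
            inv = random_inventory(6, (1.0, 500.0), (0.5, 2000.0), seed=seed)
            impurity = inv.symbols[0]
            res = purity_time(inv, impurity, product=inv.symbols[1])
            oracle = scan_oracle_release_time(inv, impurity)
            if oracle is None:
                assert not res.found or res.already_pure
                continue
            hits += 1
            if res.already_pure:
                assert oracle <= 0.52
            else:
                assert res.release_time == pytest.approx(oracle, abs=0.02)
        assert hits >= 3  # the comparison actually exercised crossings


def test_misaligned_entry_key_rejected():
    with pytest.raises(ValueError, match="does not match"):
        ActivityInventory(entries={"I-124": (Nuclide("I-123", 13.2, "h"), 1.0)})
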