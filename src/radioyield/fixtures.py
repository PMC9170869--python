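"""Bundled reference datasets from a published Monte Carlo study of
cyclotron I-124 production on TeO2 solid targets (IBA 18/9-class machine,
18 MeV protons degraded to 14.8 MeV with 0.2 mm Havar, 1.5 h runs at 10
or 15 uA, natural and Te-124-enriched targets).

Each fixture transcribes a printed table cell-for-cell and exists so the
whole pipeline can be exercised and checked without any download:

- ``enriched_10uA`` / ``enriched_15uA`` / ``natural_10uA`` / ``natural_15uA``:
  simulated end-of-bombardment activity inventories. The printed
  activities are quantized to 1 uCi = 0.037 MBq. Half-lives are stored as
  printed (rounded); pass ``half_lives="evaluated"`` to decay with the
  bundled evaluated constants instead.
- ``eos_comparison``: per-run end-of-separation times, measured and
  simulated activities and the experiment-versus-simulation difference.
- ``purity_reference``: release times and activities at the Ph. Eur.
  I-123 <= 0.35% purity point.
- ``foil_properties``, ``target_masses``, ``natural_te_abundances``,
  ``separation_runs``: degrader foil data, target mass ladder, natural Te
  isotopic composition and product/waste separation activities.
"""

from __future__ import annotations

import pandas as pd

from .inventory import ActivityInventory
from .nuclides import NUCLIDE_TABLE, Nuclide

#: 1 uCi in MBq; the resolution of the printed inventory activities.
PRINTED_ACTIVITY_QUANTUM_MBQ = 0.037

# (symbol, half-life, unit, EOB MBq, after-72h MBq, after-72h %)
_INV_ENRICHED_10UA = [
    ("He-6", 806.7, "ms", 72.483, 0.0, 0.0),
    ("I-119", 19.1, "min", 138.010, 0.0, 0.0),
    ("I-120", 81.6, "min", 76.664, 0.0, 0.0),
    ("I-122", 3.6, "min", 717.393, 0.0, 0.0),
    ("I-123", 13.2, "h", 672.623, 15.429, 10.38),
    ("I-124", 4.2, "d", 214.711, 130.499, 87.71),
    ("N-13", 9.9, "min", 3794.831, 0.0, 0.0),
    ("O-14", 70.6, "s", 143.449, 0.0, 0.0),
    ("Sb-119", 38.2, "h", 3.848, 1.036, 0.70),
    ("Sb-122", 2.7, "d", 1.147, 0.518, 0.35),
    ("Te-119", 16.1, "h", 8.991, 0.407, 0.27),
    ("Te-121", 19.2, "d", 0.962, 0.888, 0.59),
]
_TOTALS_ENRICHED_10UA = (5845.112, 148.777)

_INV_ENRICHED_15UA = [
    ("I-118", 13.7, "min", 71.447, 0.0, 0.0),
    ("I-119", 19.1, "min", 69.449, 0.0, 0.0),
    ("I-120", 81.6, "min", 77.182, 0.0, 0.0),
    ("I-121", 2.12, "h", 223.904, 0.0, 0.0),
    ("I-122", 3.6, "min", 1732.821, 0.0, 0.0),
    ("I-123", 13.2, "h", 1151.958, 26.455, 11.46),
    ("I-124", 4.2, "d", 332.334, 201.983, 87.50),
    ("N-13", 9.9, "min", 4972.319, 0.0, 0.0),
    ("Sb-118", 3.6, "min", 72.187, 0.0, 0.0),
    ("Sb-119", 38.2, "h", 1.924, 0.518, 0.23),
    ("Te-118", 6.0, "d", 0.518, 0.370, 0.16),
    ("Te-119", 16.1, "h", 4.514, 0.185, 0.09),
    ("Te-121", 19.2, "d", 1.480, 1.332, 0.57),
]
_TOTALS_ENRICHED_15UA = (8712.02, 230.843)

_INV_NATURAL_10UA = [
    ("Be-11", 13.8, "s", 72.483, 0.0, 0.0),
    ("He-6", 806.7, "ms", 72.483, 0.0, 0.0),
    ("I-120", 81.6, "min", 38.739, 0.0, 0.0),
    ("I-122", 3.6, "min", 434.972, 0.0, 0.0),
    ("I-123", 13.2, "h", 65.786, 1.517, 4.44),
    ("I-124", 4.2, "d", 23.199, 14.097, 41.47),
    ("I-125", 59.4, "d", 3.552, 3.404, 10.06),
    ("I-126", 12.9, "d", 14.319, 12.173, 35.84),
    ("I-128", 24.9, "min", 3326.115, 0.0, 0.0),
    ("I-130", 12.4, "h", 157.916, 2.775, 8.19),
    ("N-13", 9.9, "min", 3979.609, 0.0, 0.0),
    ("O-14", 70.6, "s", 72.483, 0.0, 0.0),
    ("O-15", 122.2, "s", 72.483, 0.0, 0.0),
    ("Te-129", 69.6, "min", 42.92, 0.0, 0.0),
]
_TOTALS_NATURAL_10UA = (8377.059, 33.966)

_INV_NATURAL_15UA = [
    ("He-6", 806.7, "ms", 71.817, 0.0, 0.0),
    ("I-119", 19.1, "min", 69.079, 0.0, 0.0),
    ("I-120", 81.6, "min", 38.406, 0.0, 0.0),
    ("I-121", 2.12, "h", 111.370, 0.0, 0.0),
    ("I-122", 3.6, "min", 1221.111, 0.0, 0.0),
    ("I-123", 13.2, "h", 70.596, 1.628, 3.23),
    ("I-124", 4.2, "d", 35.594, 21.608, 43.13),
    ("I-125", 59.4, "d", 3.996, 3.848, 7.66),
    ("I-126", 12.9, "d", 17.316, 14.726, 29.38),
    ("I-128", 24.9, "min", 5404.738, 0.0, 0.0),
    ("I-130", 12.4, "h", 361.527, 6.364, 12.72),
    ("N-13", 9.9, "min", 5161.833, 0.0, 0.0),
    ("O-14", 70.6, "s", 143.671, 0.0, 0.0),
    ("Sb-119", 38.2, "h", 1.928, 0.518, 1.04),
    ("Sb-122", 2.7, "d", 1.147, 0.518, 1.05),
    ("Te-119", 16.1, "h", 4.514, 0.185, 0.40),
    ("Te-121", 19.2, "d", 0.666, 0.592, 1.16),
    ("Te-127", 9.4, "h", 22.681, 0.111, 0.22),
    ("Te-129", 66.6, "min", 42.513, 0.0, 0.0),
]
_TOTALS_NATURAL_15UA = (12784.503, 50.098)

_INVENTORIES = {
    "enriched_10uA": (_INV_ENRICHED_10UA, _TOTALS_ENRICHED_10UA),
    "enriched_15uA": (_INV_ENRICHED_15UA, _TOTALS_ENRICHED_15UA),
    "natural_10uA": (_INV_NATURAL_10UA, _TOTALS_NATURAL_10UA),
    "natural_15uA": (_INV_NATURAL_15UA, _TOTALS_NATURAL_15UA),
}

# Per-run EOS comparison: run number, beam current, EOB-to-EOS time,
# measured activity, simulated activity (entry-wise-decayed inventory total
# at EOS), printed |sim-exp|/exp difference.
_EOS_COMPARISON = [
    # run, current_uA, time_h, experimental_MBq, simulated_MBq, difference_pct
    (1, 10, 73.88, 20.72, 33.30, 60.71),
    (2, 10, 118.14, 13.69, 24.79, 81.08),
    (3, 10, 122.77, 14.43, 24.42, 69.23),
    (4, 10, 96.50, 18.50, 28.12, 52.00),
    (5, 10, 131.36, 15.91, 23.68, 48.83),
    (6, 10, 72.39, 20.72, 34.04, 64.28),
    (7, 10, 70.44, 25.16, 34.41, 36.76),
    (8, 10, 70.89, 23.31, 34.41, 47.62),
    (9, 10, 144.87, 14.43, 22.20, 53.85),
    (10, 15, 71.49, 56.61, 50.32, 11.11),
]

# Release point at the Ph. Eur. I-123 <= 0.35% purity threshold.
# The natural/10 uA row's printed I-123 activity (0.74 MBq) is
# inconsistent with decay arithmetic (expected ~0.08 MBq) and is kept
# as printed; the other three rows are arithmetically consistent.
_PURITY_REFERENCE = [
    # target, current_uA, time_h, I124_MBq, I124_pct, I123_MBq, I123_pct
    ("natural", 10, 127.0, 9.624, 40.23, 0.74, 0.35),
    ("natural", 15, 122.0, 15.318, 45.25, 0.111, 0.35),
    ("enriched", 10, 149.0, 76.627, 98.01, 0.259, 0.35),
    ("enriched", 15, 151.0, 117.327, 98.34, 0.407, 0.35),
]

_FOIL_PROPERTIES = {
    # thermal conductivity W/(m K), melting point degC, density g/cm^3
    "Al": {"thermal_conductivity": 167.0, "melting_point": 582.0, "density": 2.7},
    "Mo": {"thermal_conductivity": 138.0, "melting_point": 2620.0, "density": 10.2},
    "Havar": {"thermal_conductivity": 13.0, "melting_point": 1480.0, "density": 8.3},
}

_TARGET_MASSES = {  # thickness mm -> TeO2 mass mg for the 12 mm cavity
    1.0: 640.9,
    0.8: 512.7,
    0.5: 320.5,
    0.3: 192.3,
    0.1: 64.1,
}

_NATURAL_TE_ABUNDANCES = {  # percent
    "Te-120": 0.09,
    "Te-122": 2.55,
    "Te-123": 0.89,
    "Te-124": 4.74,
    "Te-125": 7.07,
    "Te-126": 18.84,
    "Te-128": 31.74,
    "Te-130": 34.08,
}

# Product (P) and waste (W) activities at end of separation per run.
_SEPARATION_RUNS = [
    # run, current_uA, product_MBq, waste_MBq
    (1, 10, 16.28, 4.44),
    (2, 10, 10.36, 3.70),
    (3, 10, 13.69, 1.11),
    (4, 10, 17.76, 0.74),
    (5, 10, 11.84, 4.07),
    (6, 10, 17.39, 3.33),
    (7, 10, 24.42, 0.74),
    (8, 10, 22.20, 1.11),
    (9, 10, 12.95, 1.48),
    (10, 15, 52.17, 4.07),
]


def _build_inventory(name: str, half_lives: str) -> ActivityInventory:
    rows, _ = _INVENTORIES[name]
    entries = {}
    for symbol, hl, unit, eob, _a72, _p72 in rows:
        if half_lives == "printed":
            nuc = Nuclide(symbol, hl, unit)
        elif half_lives == "evaluated":
            nuc = NUCLIDE_TABLE.get(symbol) or Nuclide(symbol, hl, unit)
        else:
            raise ValueError("half_lives must be 'printed' or 'evaluated'")
        entries[symbol] = (nuc, eob)
    return ActivityInventory(entries=entries, reference_time=0.0)


def inventory_reference_values(name: str) -> pd.DataFrame:
    """Printed EOB and after-72-h reference columns for an inventory fixture."""
    rows, totals = _INVENTORIES[name]
    frame = pd.DataFrame(
        rows,
        columns=["symbol", "half_life", "unit", "eob_MBq", "after72_MBq", "after72_pct"],
    )
    frame.attrs["total_eob_MBq"] = totals[0]
    frame.attrs["total_after72_MBq"] = totals[1]
    return frame


def list_fixtures() -> list[str]:
    return sorted(
        list(_INVENTORIES)
        + [
            "eos_comparison",
            "purity_reference",
            "foil_properties",
            "target_masses",
            "natural_te_abundances",
            "separation_runs",
        ]
    )


def load_fixture(name: str, half_lives: str = "printed"):
    """Load a bundled fixture by name.

    Inventory fixtures return :class:`ActivityInventory` (EOB reference
    time); tabular fixtures return DataFrames or dicts. Unknown names
    raise ``KeyError`` listing what is available.
    """
    if name in _INVENTORIES:
        return _build_inventory(name, half_lives)
    if name == "eos_comparison":
        return pd.DataFrame(
            _EOS_COMPARISON,
            columns=["run", "current_uA", "time_h", "experimental_MBq",
                     "simulated_MBq", "difference_pct"],
        )
    if name == "purity_reference":
        return pd.DataFrame(
            _PURITY_REFERENCE,
            columns=["target", "current_uA", "time_h", "I124_MBq", "I124_pct",
                     "I123_MBq", "I123_pct"],
        )
    if name == "foil_properties":
        return pd.DataFrame(_FOIL_PROPERTIES).T
    if name == "target_masses":
        return dict(_TARGET_MASSES)
    if name == "natural_te_abundances":
        return dict(_NATURAL_TE_ABUNDANCES)
    if name == "separation_runs":
        return pd.DataFrame(
            _SEPARATION_RUNS,
            columns=["run", "current_uA", "product_MBq", "waste_MBq"],
        )
    raise KeyError(f"unknown fixture {name!r}; available: {list_fixtures()}")
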