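"""Nuclide constants and the bookkeeping unit of all activity inventories.

A :class:`Nuclide` carries a symbol, a half-life with an explicit unit and
optional decay-mode branching. The bundled :data:`NUCLIDE_TABLE` holds
NNDC-style evaluated values for the species produced in proton irradiation
of tellurium-dioxide targets; reproduction of specific published
inventories may override half-lives per run (published tables often round,
e.g. 4.2 d versus the evaluated 4.176 d for I-124).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import pandas as pd

from .units import HOURS_PER_UNIT, hours

LN2 = math.log(2.0)

#: decay mode tag, branching percent (None when the source gives no split)
DecayMode = tuple[str, float | None]


@dataclass(frozen=True)
class Nuclide:
    symbol: str
    half_life: float
    half_life_unit: str = "h"
    decay_modes: tuple[DecayMode, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.half_life_unit not in HOURS_PER_UNIT:
            raise ValueError(
                f"nuclide {self.symbol}: unknown half-life unit "
                f"{self.half_life_unit!r}"
            )
        if not self.half_life > 0:
            raise ValueError(
                f"nuclide {self.symbol}: half-life must be positive, "
                f"got {self.half_life}"
            )
        percents = [p for _, p in self.decay_modes if p is not None]
        if percents and len(percents) == len(self.decay_modes):
            total = sum(percents)
            if abs(total - 100.0) > 0.01:
                raise ValueError(
                    f"nuclide {self.symbol}: branching percentages sum to "
                    f"{total}, expected 100 +- 0.01"
                )

    @property
    def half_life_h(self) -> float:
        return hours(self.half_life, self.half_life_unit)

    @property
    def decay_constant(self) -> float:
        """ln 2 / T1/2, in h^-1."""
        return LN2 / self.half_life_h

    def with_half_life(self, half_life: float, unit: str) -> "Nuclide":
        """Copy with an overridden half-life (per-run table overrides)."""
        return Nuclide(self.symbol, half_life, unit, self.decay_modes)


def _n(symbol: str, hl: float, unit: str, *modes: DecayMode) -> Nuclide:
    return Nuclide(symbol, hl, unit, tuple(modes))


#: Bundled evaluated nuclide constants (version 1).
NUCLIDE_TABLE_VERSION = "1"

NUCLIDE_TABLE: dict[str, Nuclide] = {
    n.symbol: n
    for n in [
        _n("He-6", 806.7, "ms", ("B-", None)),
        _n("Be-11", 13.76, "s", ("B-", None)),
        _n("N-13", 9.965, "min", ("EC B+", None)),
        _n("O-14", 70.62, "s", ("EC B+", None)),
        _n("O-15", 122.24, "s", ("EC B+", None)),
        _n("F-18", 109.77, "min", ("EC B+", None)),
        _n("Sb-118", 3.6, "min", ("EC B+", None)),
        _n("Sb-119", 38.19, "h", ("EC", None)),
        _n("Sb-122", 2.7238, "d", ("B-", 97.59), ("EC B+", 2.41)),
        _n("Te-118", 6.0, "d", ("EC", None)),
        _n("Te-119", 16.05, "h", ("EC B+", None)),
        _n("Te-121", 19.17, "d", ("EC B+", None)),
        _n("Te-127", 9.35, "h", ("B-", None)),
        _n("Te-129", 69.6, "min", ("B-", None)),
        _n("I-118", 13.7, "min", ("EC B+", None)),
        _n("I-119", 19.1, "min", ("EC B+", None)),
        _n("I-120", 81.6, "min", ("EC B+", None)),
        _n("I-121", 2.12, "h", ("EC B+", None)),
        _n("I-122", 3.63, "min", ("EC B+", None)),
        _n("I-123", 13.2235, "h", ("EC B+", None)),
        _n("I-124", 4.176, "d", ("EC B+", None)),
        _n("I-125", 59.407, "d", ("EC", None)),
        _n("I-126", 12.93, "d", ("EC B+", 52.7), ("B-", 47.3)),
        _n("I-128", 24.99, "min", ("B-", 93.1), ("EC B+", 6.9)),
        _n("I-130", 12.36, "h", ("B-", None)),
    ]
}


def get_nuclide(symbol: str) -> Nuclide:
    try:
        return NUCLIDE_TABLE[symbol]
    except KeyError:
        raise KeyError(
            f"unknown nuclide {symbol!r}; bundled nuclides: {sorted(NUCLIDE_TABLE)}"
        ) from None


def _parse_decay_modes(spec: str | float | None) -> tuple[DecayMode, ...]:
    if spec is None or (isinstance(spec, float) and math.isnan(spec)) or spec == "":
        return ()
    modes: list[DecayMode] = []
    for part in str(spec).split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            tag, pct = part.rsplit(":", 1)
            modes.append((tag.strip(), float(pct)))
        else:
            modes.append((part, None))
    return tuple(modes)


def _format_decay_modes(modes: tuple[DecayMode, ...]) -> str:
    return ";".join(tag if pct is None else f"{tag}:{pct}" for tag, pct in modes)


def load_nuclide_table(source) -> list[Nuclide]:
    """Read nuclides from CSV with header ``symbol,half_life,unit,decay_modes``.

    ``source`` is a path or text buffer. Duplicate symbols and invalid rows
    raise ``ValueError`` naming the offending row.
    """
    frame = pd.read_csv(source)
    required = {"symbol", "half_life", "unit"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"nuclide table missing columns: {sorted(missing)}")
    nuclides: list[Nuclide] = []
    seen: set[str] = set()
    for idx, row in frame.iterrows():
        symbol = str(row["symbol"])
        if symbol in seen:
            raise ValueError(f"row {idx}: duplicate nuclide symbol {symbol!r}")
        seen.add(symbol)
        try:
            modes = _parse_decay_modes(row.get("decay_modes"))
            nuclides.append(Nuclide(symbol, float(row["half_life"]), str(row["unit"]), modes))
        except ValueError as exc:
            raise ValueError(f"row {idx} ({symbol}): {exc}") from None
    return nuclides


def dump_nuclide_table(nuclides: list[Nuclide]) -> str:
    """Serialize nuclides to the CSV format read by :func:`load_nuclide_table`."""
    buf = io.StringIO()
    frame = pd.DataFrame(
        {
            "symbol": [n.symbol for n in nuclides],
            "half_life": [n.half_life for n in nuclides],
            "unit": [n.half_life_unit for n in nuclides],
            "decay_modes": [_format_decay_modes(n.decay_modes) for n in nuclides],
        }
    )
    frame.to_csv(buf, index=False)
    return buf.getvalue()
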