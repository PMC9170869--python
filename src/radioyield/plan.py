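"""End-to-end production plan: degrade -> window -> yield -> decay -> purity.

:func:`run_plan` chains the pipeline stages into one machine-readable
report. Every numeric in the report carries its unit in the key name, and
the configuration (including the seed) is echoed so a rerun of the echoed
configuration reproduces the report byte for byte apart from timestamps
(the report itself carries none).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .activation import CrossSectionTable, TargetSpec, thick_target_eob_activity
from .beam import BeamSpec
from .inventory import ActivityInventory, purity_time
from .materials import Material
from .stopping import STOPPED, StoppingModel


class PlanStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    beam: BeamSpec
    target: TargetSpec
    xs: list[CrossSectionTable] = field(default_factory=list)
    foil: tuple[Material, float] | None = None  # (material, thickness mm)
    inventory: ActivityInventory | None = None
    decay_times_h: list[float] = field(default_factory=list)
    impurity: str | None = None
    purity_threshold: float = 0.0035
    seed: int = 0

    def echo(self) -> dict:
        doc: dict = {
            "beam": {
                "energy_MeV": self.beam.energy,
                "current_uA": self.beam.current,
                "irradiation_time_h": self.beam.irradiation_time,
            },
            "target": {
                "material": self.target.material.name,
                "thickness_mm": self.target.thickness_mm,
                "parent_isotope": self.target.parent_isotope,
                "parent_abundance": self.target.parent_abundance,
            },
            "xs_channels": [t.channel for t in self.xs],
            "decay_times_h": list(self.decay_times_h),
            "impurity": self.impurity,
            "purity_threshold": self.purity_threshold,
            "seed": self.seed,
        }
        if self.foil is not None:
            doc["foil"] = {
                "material": self.foil[0].name,
                "thickness_mm": self.foil[1],
            }
        return doc


def run_plan(config: RunConfig, stopping: StoppingModel | None = None) -> dict:
    """Execute the pipeline described by ``config`` and return the report."""
    stopping = stopping or StoppingModel()
    report: dict = {"config": config.echo(), "units": {
        "energy": "MeV", "activity": "MBq", "yield": "MBq/uAh",
        "time": "h", "length": "mm",
    }}

    # 1. degrade through the foil
    beam = config.beam
    if config.foil is not None:
        foil_material, foil_mm = config.foil
        try:
            degraded = stopping.energy_after_slab(foil_material, foil_mm, beam.energy)
        except ValueError as exc:
            raise PlanStageError("degrade", str(exc)) from exc
        if degraded is STOPPED:
            raise PlanStageError(
                "degrade",
                f"beam stopped in {foil_material.name} foil of {foil_mm} mm",
            )
        report["degraded_energy_MeV"] = degraded
        beam = BeamSpec(degraded, beam.current, beam.irradiation_time)
    else:
        report["degraded_energy_MeV"] = beam.energy

    # 2. energy window in the target
    window = stopping.energy_window_in_target(
        config.target.material, config.target.thickness_mm, beam.energy
    )
    report["energy_window_MeV"] = {
        "in": window.energy_in,
        "out": window.energy_out,
        "fully_stopped": window.fully_stopped,
    }

    # 3. activation per channel
    channels = {}
    for xs in config.xs:
        try:
            res = thick_target_eob_activity(xs, config.target, beam, stopping)
        except ValueError as exc:
            raise PlanStageError("yield", f"{xs.channel}: {exc}") from exc
        channels[xs.channel] = {
            "eob_MBq": res.eob_activity,
            "saturation_MBq": res.saturation_activity,
            "yield_MBq_per_uAh": res.yield_per_uah,
            "window_clipped": res.window_clipped,
        }
    report["channels"] = channels

    # 4. decay trajectory of the supplied inventory
    if config.inventory is not None:
        trajectory = {}
        for dt in config.decay_times_h:
            decayed = config.inventory.decay(dt)
            trajectory[f"{dt:g}"] = {
                "total_MBq": decayed.total(),
                "per_nuclide_MBq": {
                    s: decayed.activity(s) for s in decayed.symbols
                },
            }
        report["decay_trajectory_h"] = trajectory

        # 5. purity planning
        if config.impurity is not None:
            try:
                purity = purity_time(
                    config.inventory, config.impurity,
                    threshold=config.purity_threshold,
                )
            except KeyError as exc:
                raise PlanStageError("purity", str(exc)) from exc
            report["purity"] = {
                "found": purity.found,
                "release_time_h": purity.release_time,
                "product_MBq": purity.product_activity,
                "impurity_MBq": purity.impurity_activity,
                "impurity_fraction": purity.impurity_fraction,
                "already_pure": purity.already_pure,
            }
    return report
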