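"""Thick-target activation yield with the calibrated toy excitation function.

Integrates sigma(E) across the in-target energy window for a 0.5 mm TeO2
layer irradiated with 14.8 MeV protons (10 uA, 1.5 h), then shows the
exact linear scaling from natural (4.74% Te-124) to enriched (99.5%)
target material. The toy sigma(E) is a Gaussian anchored at 300 mb @
14 MeV with a 3x drop at 18 MeV; absolute yields are therefore
illustrative, the scalings are exact.
"""

from radioyield import BeamSpec, StoppingModel, calibrated_toy_xs, teo2_target, thick_target_eob_activity

model = StoppingModel()
xs = calibrated_toy_xs()
beam = BeamSpec(energy=14.8, current=10.0, irradiation_time=1.5)

for label, abundance in [("natural", 0.0474), ("enriched", 0.995)]:
    target = teo2_target(0.5, abundance=abundance)
    res = thick_target_eob_activity(xs, target, beam, model)
    e_in, e_out = res.energy_window
    print(f"{label:9s}: window {e_in:.1f} -> {e_out:.1f} MeV, "
          f"EOB {res.eob_activity:8.2f} MBq, "
          f"yield {res.yield_per_uah:6.3f} MBq/uAh")

print("\nEOB activity is linear in abundance (x21 from 4.74% to 99.5%) and in")
print("beam current; the (1 - e^(-lambda t)) saturation factor caps long runs.")
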