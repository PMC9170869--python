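"""Degrader-foil energy loss and proton range in a TeO2 target.

An 18 MeV cyclotron beam is moderated onto the useful part of the
Te-124(p,n)I-124 excitation function with a thin metal foil. This example
degrades the beam through each bundled foil material and reports the CSDA
range of the degraded beam in TeO2 glass.
"""

from radioyield import STOPPED, StoppingModel, aluminum, havar, molybdenum, tellurium_dioxide

model = StoppingModel()
teo2 = tellurium_dioxide()

print("18 MeV protons through 0.2 mm foils:")
for foil in (havar(), molybdenum(), aluminum()):
    out = model.energy_after_slab(foil, 0.2, 18.0)
    label = "stopped" if out is STOPPED else f"{out:.2f} MeV"
    print(f"  {foil.name:6s} (rho={foil.density:5.2f} g/cm3) -> {label}")

exit_energy = model.energy_after_slab(havar(), 0.2, 18.0)
range_um = model.csda_range(teo2, exit_energy)
print(f"\nCSDA range of {exit_energy:.2f} MeV protons in TeO2 glass: {range_um:.0f} um")
print("A target thicker than this range absorbs the beam completely; the")
print("denser the foil, the thinner the layer needed for the same energy drop.")
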