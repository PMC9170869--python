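"""Straggled stopping-depth distribution of 14.8 MeV protons in TeO2.

Samples a Gaussian depth distribution with the Bohr range-straggling
variance around the CSDA range -- a quick stand-in for condensed-history
transport that locates the stopping peak and its width.
"""

from radioyield import StoppingModel, tellurium_dioxide

model = StoppingModel()
teo2 = tellurium_dioxide()

dist = model.simulate_range_distribution(teo2, 14.8, n_protons=100_000, seed=1)
print(f"CSDA range            : {model.csda_range(teo2, 14.8):.1f} um")
print(f"sampled mode          : {dist.mode:.1f} um")
print(f"sampled mean +- sd    : {dist.mean:.1f} +- {dist.sd:.1f} um")
print("The mode marks where most protons stop: targets thinner than this")
print("transmit the beam, markedly thicker ones absorb it completely.")
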