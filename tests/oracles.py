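"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's tabulated/interpolated code paths:
constants come from scipy.constants, integration is fixed-step trapezoid,
and the activation oracle steps through the target depth slab by slab.
"""

import math

import numpy as np
from scipy import constants as sc

E_CHARGE = 1.602176634e-19


def oracle_mass_stopping(material, energy):
    """Bethe mass stopping power re-derived from scipy.constants, MeV cm^2/g."""
    mec2 = sc.physical_constants["electron mass energy equivalent in MeV"][0]
    mpc2 = sc.physical_constants["proton mass energy equivalent in MeV"][0]
    re_cm = sc.physical_constants["classical electron radius"][0] * 100.0
    k = 4.0 * math.pi * sc.Avogadro * re_cm**2 * mec2  # MeV cm^2 / mol
    gamma = 1.0 + energy / mpc2
    beta2 = 1.0 - 1.0 / gamma**2
    i_mev = material.mean_excitation_energy * 1e-6
    log_term = math.log(2.0 * mec2 * beta2 * gamma**2 / i_mev)
    za = material.electrons_per_gram / sc.Avogadro
    return k * za / beta2 * (log_term - beta2)


def oracle_csda_range_um(material, energy, cutoff=0.25, step_mev=0.001):
    """Fixed 1 keV-step trapezoid integration of the inverse stopping power."""
    e = np.arange(cutoff, energy + step_mev / 2, step_mev)
    inv = np.array([1.0 / oracle_mass_stopping(material, x) for x in e])
    return np.trapezoid(inv, e) / material.density * 1e4


def slab_oracle_eob_mbq(xs, target, beam, model, slab_um=1.0):
    """Depth-stepping activation oracle: sigma at each slab-entry energy."""
    from radioyield import STOPPED

    rho = target.material.density
    n_atoms_g = target.parent_atoms_per_gram
    energy = beam.energy
    depth = 0.0
    reactions_per_proton = 0.0
    slab_mm = slab_um / 1000.0
    while depth < target.thickness_mm:
        step_mm = min(slab_mm, target.thickness_mm - depth)
        sigma_cm2 = float(xs.sigma_at(energy)) * 1e-27
        reactions_per_proton += n_atoms_g * sigma_cm2 * rho * step_mm * 0.1
        nxt = model.energy_after_slab(target.material, step_mm, energy)
        if nxt is STOPPED:
            break
        energy = nxt
        depth += step_mm
    rate = beam.current * 1e-6 / E_CHARGE * reactions_per_proton
    lam = xs.product.decay_constant
    return rate * (1.0 - np.exp(-lam * beam.irradiation_time)) / 1e6


def scan_oracle_release_time(inv, impurity, threshold=0.0035, t_max=1000.0, step=0.01):
    """Brute-force scan for the first time the impurity fraction <= threshold."""
    symbols = inv.symbols
    a0 = np.array([inv.activity(s) for s in symbols])
    lam = np.array([inv.nuclide(s).decay_constant for s in symbols])
    i = symbols.index(impurity)
    ts = np.arange(0.5, t_max, step)
    acts = a0[:, None] * np.exp(-lam[:, None] * ts[None, :])
    frac = acts[i] / acts.sum(axis=0)
    below = np.nonzero(frac <= threshold)[0]
    return float(ts[below[0]]) if below.size else None
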