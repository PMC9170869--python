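# Methods

## Scope and model chain

The package models the computational side of solid-target radionuclide
production on a small medical cyclotron: beam degradation in foils,
proton stopping and range in the target, thick-target activation of a
production channel, decay evolution of the resulting activity inventory,
and release-time planning against a radionuclidic-purity limit. Nuclear
data (excitation functions, half-lives) are inputs; no nuclear-model
calculation, particle transport beyond the continuous-slowing-down
picture, target thermal behaviour, or separation chemistry is modelled.

## Stopping power and range

Electronic stopping follows the relativistic Bethe formula without shell
or density-effect corrections:

    -dE/d(ρx) = K ⟨Z/A⟩ z²/β² [ ln(2 m_e c² β² γ² / I) − β² ]

with K = 4π N_A r_e² m_e c² ≈ 0.307 MeV cm²/mol derived at run time from
CODATA constants (Coulomb constant, elementary charge, electron rest
energy), β² from the proton kinetic energy via γ = 1 + E/m_p c², and the
compound mean excitation energy I from Bragg additivity on ln I weighted
by electron fraction. Element I values follow the ICRU-49 recommended
list. For 1–30 MeV protons the omitted corrections bias stopping by a
few percent at the low-energy end; since most of the path is spent at
high energy the net range bias is smaller, and the package's TeO₂ range
at 14.8 MeV (782 μm) sits ~4% below the SRIM-class reference value
(813 μm), well inside the ±7% accuracy bound we attach to ranges.

The CSDA range is R(E₀) = ∫ S(E)⁻¹ dE accumulated by trapezoid on a
2 keV grid from a low-energy cutoff (default 0.25 MeV; the Bethe
logarithm degenerates below ~0.1 MeV) with monotone PCHIP interpolation
between nodes in both directions (energy→range and range→energy). The
sub-cutoff residual range (~2 μm in TeO₂) is set to zero. Tests hold the
tabulated path to a 1 keV fixed-step brute-force integrator within 0.1%.
The declared validity window is 1–30 MeV for beams and
cutoff–30 MeV for evaluations; outside it the model raises rather than
extrapolates.

Slab transmission uses range inversion, E_out = R⁻¹(R(E_in) − ρt).
A beam whose residual range is exhausted (or whose exit energy falls
below the cutoff) returns an explicit `STOPPED` outcome rather than an
exception, because thickness sweeps legitimately cross that point.

### Range straggling

`simulate_range_distribution` draws stopping depths from a Gaussian
centred on the CSDA range with the non-relativistic Bohr variance

    σ_R² = ∫ (dΩ²/dρx) S(E)⁻³ dE,  dΩ²/dρx = K m_e c² ⟨Z/A⟩ z².

This is an explicit approximation to condensed-history transport: it
reproduces the location and width of the stopping peak (~11 μm sd in
TeO₂ at 14.8 MeV, versus 15–24 μm from full transport codes) but not
energy-loss tails, lateral spread or nuclear attenuation. It is excluded
from quantitative checks except for bracketing the stopping-peak
location; the seed is a mandatory argument and fully determines the
histogram (bin width 2 μm, mode = densest bin centre, ties to the
shallowest bin).

## Activation

For a channel with excitation function σ(E) and a parent isotope of
molar mass M, element mass fraction w and isotopic abundance f_a, the
end-of-bombardment activity over the in-target window [E_out, E_in] is

    A_EOB = (I/e)(1 − e^(−λ t_irr)) · (N_A w f_a / M) · ∫ σ(E) S(E)⁻¹ dE.

σ(E) is linearly interpolated on its grid and zero outside it (no
extrapolation; windows clipped by the grid are flagged). The quadrature
is trapezoid on a dense (~2000-node) grid joined with the σ grid nodes,
so the piecewise-linear σ is integrated exactly up to stopping-power
curvature; tests hold it to a 1 μm depth-slab oracle within 0.5% and to
the thin-target closed form A = (I/e)(1−e^(−λt)) n_areal σ within 0.1%.
Each (p,xn) channel is computed independently from its own σ table;
beam attenuation and secondary-neutron reactions are neglected, which is
standard at these fluences.

Consequences used as test invariants: activity is exactly linear in beam
current and in parent abundance (enrichment from 4.74% natural ¹²⁴Te to
~99.5% scales yield by exactly the abundance ratio), and monotonically
saturating in irradiation time with asymptote A_sat = rate.

## Inventories, decay and purity

Inventories map nuclide → activity at a reference time (0 = end of
bombardment). Decay is entry-wise exponential, A(t) = A₀ 2^(−t/T½); no
parent→daughter ingrowth is modelled. This matches how the bundled
reference inventories were constructed (their after-72 h columns are
exactly entry-wise decay of the EOB columns) and is adequate for the
iodine/tellurium species here, whose feeding chains contribute below the
print resolution on these time scales. Entries decaying below 10⁻⁶ MBq
are retained but flagged negligible.

The purity planner finds the first time the impurity's share of *total*
remaining activity falls to a threshold (default 0.35%, the Ph. Eur.
limit for ¹²³I in ¹²⁴I preparations): a 0.5 h forward scan over the
bracket (default 0.5–1000 h) locates the first downward crossing, then
60 plain bisection steps shrink the interval far below the 0.01 h
comparison resolution, so the returned fraction sits within 10⁻⁶ of the
threshold. A trajectory that never crosses inside the bracket returns an
explicit no-solution result carrying the fraction range seen; an
inventory already at or below the threshold returns the bracket start as
an already-pure result. A single downward crossing is assumed within the
bracket (true for these inventories, where the impurity outdecays the
product); the first-crossing scan plus a brute-force scan oracle in the
tests guard the general case.

The experiment-versus-simulation statistic is |sim − exp|/exp · 100,
verified against every printed row of the bundled comparison table.

## Nuclide and material data

Nuclide constants ship as a versioned bundled table of NNDC-style
evaluated values (e.g. ¹²⁴I 4.176 d, ¹²³I 13.2235 h, ¹³⁰I 12.36 h).
The bundled reference inventories store the half-lives printed alongside
them — including their rounding (4.2 d) and their internal
inconsistencies (¹²⁹Te appears as 69.6 min in one table and 66.6 min in
another; both are preserved per table) — with `half_lives="evaluated"`
swapping in the evaluated constants. Reproduction tests use the
evaluated constants: the printed tables' own decay arithmetic evidently
used unrounded half-lives, and the evaluated set reproduces their
after-72 h columns to ≤1.5% everywhere above the print resolution,
whereas the printed (rounded) half-lives do not.

The printed activities are quantized to 1 μCi = 0.037 MBq (44 of 46
cells sit on that grid), so comparisons of sub-MBq cells carry a
one-quantum absolute floor alongside the 1.5% relative tolerance, and
percentage columns a 0.05 pp floor: below those resolutions the printed
values carry no information.

Havar's composition is not given alongside its 8.3 g/cm³ density; the
standard nominal alloy (Co 42.5 / Cr 20.0 / Fe 17.9 / Ni 13.0 / W 2.8 /
Mo 2.2 / Mn 1.6 wt%) is bundled and documented as an assumption. TeO₂
uses stoichiometric mass fractions at the vitreous density 5.65 g/cm³.
The enrichment level of "enriched" targets defaults to 99.5% ¹²⁴Te and
is configurable. Canonical internal units are MeV, g/cm³, cm (interfaces
in mm/μm), h, MBq and μA, with conversions centralized in one module.

## Synthetic data

The toy excitation function is a Gaussian solved in closed form from two
anchors of the ¹²⁴Te(p,n)¹²⁴I channel — σ(14 MeV) = 300 mb and
σ(14)/σ(18) = 3, peak at 13 MeV — tabulated at 0.1 MeV over 4–20 MeV.
It is analytically tractable and deliberately *not* a reproduction of
the evaluated excitation-function shape: its Gaussian symmetry
understates the real curve's low-energy side and has no (p,2n)
competition, so absolute yields and sweep optima computed with it are
illustrative. Quantitative yield claims are restricted to the anchored
constraints, analytic limits and oracle equivalences; with an evaluated
σ(E) table supplied through the CSV interface the same operations apply
unchanged. Random inventories sample half-lives and activities
log-uniformly (defaults 0.01–2000 h and 0.1–5000 MBq, emulating the
minutes-to-months, four-decade structure of real post-irradiation
inventories) from a mandatory seed.

What passing tests on synthetic data do **not** show: agreement of
absolute yields with measured production runs (that requires evaluated
cross sections and separation-efficiency corrections), or the detailed
shape of transport-code depth distributions.

## Design choices and limitations

- Corrections (shell, density effect, Barkas/Bloch) are omitted by
  design; the ±7% range band is the corresponding accuracy statement.
- σ(E) outside its grid is zero, not extrapolated — conservative and
  reproducible.
- Degraded beams that fall below the 1 MeV validity floor in a sweep are
  reported as stopped-in-foil rather than evaluated.
- The acceptance-style checks and tests run at small problem sizes
  (2 keV stopping tables, ~10⁵-sample straggling draws, 1 μm oracle
  slabs, ≤100-case randomized property sweeps), which keeps the whole
  suite at a few seconds without changing any reported physics.
- No dose, shielding, heat-deposition or distillation-efficiency
  modelling; the >75% distillation recovery seen in practice enters only
  as an optional scalar on reported activities, applied by the caller.
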