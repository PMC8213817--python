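# Methods

This note documents the models implemented in `slbfet`, the defaults
that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Binding kinetics

The equilibrium response is the single-site Langmuir isotherm
ΔV_TG = V_max·[A]/([A]+K_eq) with V_max = q_A[B]_max/C_TG.  The
time-resolved model for one injection is

    ΔV(t) = A·(1 − e^{−k_obs t}) + transient(t),  k_obs = k₁[A] + k₋₁.

Two closures for the amplitude `A` are provided:

* **verbatim** (`equilibrium_fraction=False`, default of `trace_model`):
  A = V_max.  This is the form the two-branch circuit model is usually
  quoted in, but its t→∞ plateau is V_max for *any* concentration, which
  contradicts the isotherm.
* **equilibrium-fraction** (`equilibrium_fraction=True`, default of the
  generator and the trace fitter): A = V_max·k₁[A]/k_obs, the standard
  solution of the first-order Langmuir rate equation.  Its plateau equals
  the isotherm value, so equilibrium plateaus of fitted traces are
  consistent with titration fits.  The flag documents the discrepancy
  rather than hiding it.

The RC transient charges as V_p(1−e^{−t/τ₁}) until the switch time T and
discharges with τ₂ afterwards.  As printed the two branches are
generally discontinuous at T; since a physical trace is continuous, the
discharging branch is re-referenced to the charging branch's value at T
by default (`continuous=True`).  The verbatim discontinuous form is
available, and `transient_discontinuity()` reports the jump magnitude so
fits can surface it.

**Transient defaults.**  V_p, τ₁, τ₂ and T are not reported by the
study; they are free fit parameters here.  The canonical simulation
defaults are V_p = 1 mV, τ₁ = 5 s, τ₂ = 10 s, T = 20 s: the transient is
an injection/fluid-exchange artifact of the measurement cell, which is
fast compared with sub-nanomolar binding (1/k_obs ≈ 43 s at 800 pM).
This time-scale separation is also what makes k₁ identifiable — if the
artifact is given the same time constant as binding, the two terms trade
off and no estimator can separate them (the Fisher information for k₁
collapses).  A simulation study that probes rate-constant recovery
therefore assumes a well-designed measurement with separated scales.

**Identifiability.**  A single trace at one concentration determines
only k_obs and the plateau, never k₁ and k₋₁ separately.  `fit_trace`
requires one of K_eq, k₁ or k₋₁ to be fixed (the study's own procedure:
rates were split using the isotherm-determined K_eq) and enforces
K_eq·k₁ = k₋₁ exactly in the report.  Fitting is trust-region nonlinear
least squares, staged: a 2-parameter binding-only fit over 7 log-spaced
rate starts pins k_obs and the plateau, then the full 6-parameter model
is started from a grid of transient shapes (4 switch times × 3 transient
amplitudes).  The staging exists because the full model's two saturating
exponentials admit role-swapped local minima.  Uncertainties come from
the Jacobian at the optimum.

Isotherm fitting (`fit_isotherm`) is weighted nonlinear least squares on
the Langmuir form, internally rescaled so both parameters are O(1)
(K_eq is ~1e-10 in SI molar units, which otherwise degrades the
trust-region scaling).  Degenerate inputs (all-zero responses) are
flagged, not raised.

## Reflectometry

Electron density ρ_e (e/Å³) maps to scattering length density via the
classical electron radius, SLD = r_e·ρ_e, r_e = 2.8179403×10⁻⁵ Å;
absorption is neglected (hard X-rays, thin organic films).  The beam is
incident from the ambient (water) side and
k_{z,j} = √(k_{z,0}² − 4π(SLD_j − SLD_ambient)), k_{z,0} = q/2.
Reflectivity is Parratt's recursion with Névot–Croce factors
exp(−2k_j k_{j+1} σ²); the test suite checks it against an independently
coded Abeles transfer-matrix oracle to 10⁻¹⁰ relative and against the
closed-form Fresnel limits.  z = 0 sits at the substrate (SiO₂) surface,
positive toward the outer buffer.  Interface roughness defaults to a
fixed 3 Å; freeing it is opt-in.  Each slab's roughness belongs to its
upper interface; the substrate's own surface roughness lives on the
stack (`substrate_roughness_A`).

**Fit objective.**  χ² on log₁₀R with σ propagated
(σ_logR = σ_R/(R ln10)), because reflectivity spans many decades.

**Genetic algorithm.**  Population 128, 300 generations, tournament
selection (size 3), uniform crossover (p = 0.7), per-gene Gaussian
mutation (p = 0.2) with σ = 5% of the bound width *annealed* linearly to
0.5% by the last generation, elitism 2, and 10% random immigrants per
generation, followed by a trust-region polish of the best individual of
up to 10 distinct basins.  The annealing, immigrants and multi-basin
polish are load-bearing: without them the population collapses into a
single basin and the winner's polish cannot escape it.

**Template bounds.**  The inverse problem is degenerate when adjacent
slabs have nearly equal density — in the 5-slab SLB model the
inter-leaflet gap (ρ ≈ 0.28) has almost no contrast against the tails
(ρ ≈ 0.30), so under wide (±50%) thickness bounds the gap can slide
within the tail region and produce a competitive false minimum that
traps any global optimizer tested (including differential evolution at
40× the default budget).  Templates should therefore carry the prior
structural knowledge a practitioner has: the shipped examples and tests
use ±30% bounds, under which the fitter recovers all ten free parameters
of a noiseless self-generated curve exactly.

## Electrostatics

The electron-density difference Δρ_e(z) across a binding event is
converted to charge density ρ_q = −e·Δρ_e (an excess of electrons is
negative charge; the sign is a parameter) and integrated twice:
D(z) = ∫ρ_q dz′ anchored at the boundary, E = D/(ε₀ε_r), ψ = −∫E dz′.
Grids are resampled to uniform spacing (the minimum input spacing) and
integrated with cumulative trapezoids, which converges at second order
(verified against closed-form slab, parallel-plate and Gaussian-dipole
solutions to ≤0.1% at a 0.1 Å grid).  The default boundary condition
anchors E = 0 and ψ = 0 at the substrate-side margin, matching
evaluation "at the SiO₂ surface"; the reference can be moved to the
ambient side or any grid position.

ε_r defaults to uniform 78.5 (water).  A piecewise profile (e.g. ~2 in
the tail region) can be supplied per-sample; the displacement field is
integrated first, so dielectric steps are handled.  The quantitative
link to the top gate goes through the calibrated divider ratio
α = ΔV_TG/Δψ (12.2/697 ≈ 0.0175), which absorbs the dielectric choice —
one fixed divider reproduces both reference pairs (697 → 12.2 mV and
499 → 8.73 mV) to three digits, supporting the single-divider
assumption.

The Debye length uses λ_D = √(ε₀ε_r k_B T/(2N_A e² I)) for a monovalent
electrolyte (≈ 0.304/√I nm in water at 25 °C).

## Membrane utilities

Coverage mass assumes two leaflets of area/APL lipids at the
mole-fraction-averaged molecular weight; the area per lipid defaults to
72 Å² (fluid-phase DOPC literature value).  Binding sites count
receptor lipids in the *upper* leaflet only, divided by the number of
receptor lipids one protein occupies (2 for avidin, avoiding steric
hindrance).  The effective sensing area is not derivable from the other
constants, so both quantities support inversion rather than prediction.

FRAP uses the uniform-disk 2-D diffusion closed form
f(t) = e^{−x}[I₀(x)+I₁(x)], x = 2τ_D/t, τ_D = w²/4D, evaluated with
exponentially-scaled Bessel functions for overflow safety; t = 0 is the
full-bleach limit f = 0.  An optional mobile-fraction scale m·f(t)
accommodates membranes that recover incompletely (a reported 80%
recovery at 10 min may reflect an immobile fraction or a truncated
observation window; the default assumes a fully fluid membrane, m = 1).
The default bleach radius of 25 μm is an explicit stand-in, configurable
per experiment.

## Synthetic data

The generator emulates: binding traces as superposed per-injection
segments (each referenced to its own injection time, its rate using the
cumulative concentration and its amplitude the increment of the
equilibrium amplitude, so the summed plateau equals the isotherm value
and zero-concentration control injections add only the RC transient);
titration series from the isotherm; reflectivity curves from the forward
model with relative Gaussian noise (default 2%, a stand-in for counting
statistics) and a populated σ_R column; FRAP curves from the disk model
with additive intensity noise (default 0.02); and monotone FET transfer
curves (linear or logistic) for current→voltage conversion.  Trace noise
is additive Gaussian (default σ = 0.1 mV).  Every generator is a pure
function of its parameters and a single explicit seed; there is no
global RNG state.

Not emulated: baseline drift, 1/f device noise, correlated photon noise,
beamline footprint/resolution effects, fluorescence imaging artifacts,
and multi-analyte competition.  Passing round-trip tests therefore show
estimator correctness under the stated noise model, not robustness to
every instrumental systematic.

## Problem sizes

The simulation studies use 600 s traces at 1 Hz (800 pM, 1% noise,
10 replicates), 600 s FRAP curves at 0.5 Hz (2% noise, 10 replicates),
200-point reflectivity curves over q = 0.02–0.6 Å⁻¹, and 100 random
stacks for the Parratt/transfer-matrix equivalence check.  These sizes
give sub-percent medians for the recovered parameters while keeping the
whole suite in the tens of seconds.

## Known limitations

* Per-segment trace fitting assumes earlier injections have equilibrated
  by the next injection; jointly fitting all segments is not implemented.
* The verbatim two-branch transient is discontinuous at T unless
  re-referenced; both behaviours are available but mixing them between
  generation and fitting will bias τ₂.
* GA results are deterministic only under a fixed seed and identical
  bounds; reflectometry minima depend on the template's prior bounds as
  discussed above.
* The divider model is a single linear attenuation; no frequency
  dependence or full circuit simulation.
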