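# Methods

This note records the model, its assumptions, the sign conventions, the
parameter defaults, and the design choices made where the underlying physics
left the formulation open.

## Model and assumptions

The cell is a rigid sphere of radius R with a thin membrane of thickness
d_memb ≪ R; all balances are steady or quasi-static (no spatial PDE, no
time integration — `temperature_rate` returns an instantaneous dT/dt only).
The cytosol and bath are well mixed at uniform temperatures T and T₀.

Three submodels are composed:

1. **Electrochemistry.** Nernst per-ion potentials and the GHK resting
   potential of the monovalent Na⁺/K⁺/Cl⁻ mixture. Divalent species (Ca²⁺)
   are carried through ion tables but never enter the GHK quotient; by
   default they are silently excluded (`divalent="ignore"`), or the call can
   be made strict (`"reject"`).
2. **First-law balance.** The convective heat exchange
   Q̇ = −α(T−T₀)A with a Dittus-Boelter-style correlation
   α = 0.023 Re⁰·⁸ Pr⁰·³⁵ λ/⟨R⟩ on the volume-to-area length scale
   ⟨R⟩ = V/A = R/3, equated with the internal-energy change ρcV·dT/dt and
   with the electric power J·E·A·d_memb of the sodium flux. The sodium mole
   balance divides the stored inflammatory heat ρc(T_high−T)V by the molar
   work term F·Δϕ_Na − Δh_Na + 2.3·R·T·ΔpH_Na.
3. **ELF wave mechanics.** Plane-wave radiation pressure εE²/2 = B²/2μ, a
   membrane force and potential perturbation (below), and a calibrated
   inverse-square resonance law with a fixed harmonic ratio set.

## Sign conventions

One table governs every signed quantity; each sign-carrying operation's
docstring refers back to it.

| quantity | convention |
|---|---|
| membrane potential Δϕ | cytosol minus bath; ≈ −70 mV at rest |
| membrane field E | Δϕ/d_memb; negative at rest |
| heat power Q̇ | positive into the cell; export to a cooler bath is negative |
| Na⁺ flux density J | positive for inflow |

The flux–power product couples through magnitudes, so the heat→flux
inversion divides by |E|: `sodium_flux_from_heat` returns
J = Q̇/(|E|·4πR²·d_memb), making sign(J) = sign(Q̇) for either field
orientation ("export heat ⇒ sodium outflow"). Its exact inverse is
`electric_power_sodium(J, |E|, geometry)`. Inverting with the signed field
instead would flip the flux sign at rest and break the outflow rule, which
is the physically meaningful statement.

## Orientation of ion tables

Published ion tables sometimes interchange the intra/extracellular columns
of Na⁺ and K⁺ relative to the signs of their own equilibrium-potential
column. The default `"physiological"` orientation rule therefore assigns
each known species its physiological high side — Na⁺ high outside, K⁺ high
inside, Cl⁻ and Ca²⁺ high outside — before forming any concentration
quotient; unknown species and the `"as-labeled"` rule use the stored columns
verbatim. With this rule the packaged reference table reproduces its own
+56/−89/−76 mV column and a −70 mV GHK resting potential at 310.15 K.

Two further table notes:

- The GHK equation is occasionally typeset with log₁₀ and an
  all-outside/all-inside quotient; that arrangement does not reproduce
  physiological resting potentials and is provided only as the
  `"paper-literal"` dialect for comparison. The default dialect uses the
  natural logarithm and the standard cation/anion side crossing.
- The Ca²⁺ equilibrium potential stored in the reference table (+125 mV) is
  not the Nernst value of its stored concentrations (≈ +33 mV at 310 K); it
  is carried verbatim as an annotation, and the run report prints both
  numbers without asserting agreement.

## Temperature curve

The potential-vs-temperature curve is the temperature scaling of the sodium
Nernst potential about the 37.4 °C operating point:
Δϕ(T) = (R/F)·ln([Na]_o/[Na]_i)·(T_ref − T), an affine function with slope
−1.827×10⁻⁴ V K⁻¹ for the 150/18 mol m⁻³ gradient. The molar enthalpy and
trans-membrane pH contributions of the full relation
nFdϕ = dH − T₀dS − 2.3nRT₀d(pH) are exposed as optional offsets
(`delta_h`, `delta_ph`) defaulting to zero, because no quantitative values
for them exist in the model's source data; entropy never appears
independently (T₀dS is absorbed as the heat term).

## ELF wave mechanics: scale caveat

The membrane force F = pA/(2πr) and potential perturbation Δϕ = F·A/(πεr)
are literal readings of the driving-force model; they are not dimensionally
derivable from first principles under any bracketing, so their absolute
scale should be treated as a modelling ansatz. They are deliberately
isolated behind two small functions so a mechanically derived replacement
can be dropped in without touching callers, and every downstream test
asserts only structural properties (linearity in p and F, monotonicity in
E², sign-following).

The resonance fundamental is likewise not derived from the thermal
constants: it is a calibrated inverse-square diameter law anchored at
(20 µm, 13.5 Hz), a pair that also places the 100 µm fundamental (0.54 Hz)
inside the independently quoted (0.6 ± 0.1) Hz band. The calibration pair
and the harmonic ratio set {1/7, 1/3, 1, 2, 4, 6} (recovered from the
published series 1.9/4.5/13.5/26.9/53.8/80.7 Hz, each carrying a ≈10% band)
are arguments, not constants.

## Parameters and defaults

| parameter | default | unit | note |
|---|---|---|---|
| R (gas), F | 8.314, 96485 | J mol⁻¹K⁻¹, C mol⁻¹ | rounded conventional values |
| ε₀ | 8.854×10⁻¹² | A s N⁻¹m⁻² | c is derived as 1/√(μ₀ε₀) so the E/B pressure forms agree to machine precision |
| cell radius | 10 | µm | worked-example cell (20 µm diameter) |
| membrane thickness | 4 | nm | gives −1.75×10⁷ V m⁻¹ at −70 mV |
| ρ, c | 10³, 4186 | kg m⁻³, J kg⁻¹K⁻¹ | water-like cytosol |
| λ, Re, Pr | 0.56, 0.2, 0.7 | W m⁻¹K⁻¹, –, – | tissue conductivity, creeping flow |
| T, T₀ | 37.4, 37.0 | °C | normal operating point |
| T_high | 37.8 | °C | default 0.4 K inflammatory excursion |
| Δϕ_Na, Δh_Na, ΔpH | +56 mV, −261.89 kJ mol⁻¹, 0 | | sodium row of the reference table |
| GHK permeabilities | 0.04 / 1 / 0.45 | – | Na⁺/K⁺/Cl⁻ relative to K⁺ |
| resonance calibration | (20 µm, 13.5 Hz) | | inverse-square anchor |

Interfaces accept the field's customary units (°C, mM, µm, nm, mV,
kJ mol⁻¹); everything internal is SI (K, mol m⁻³, m, V, J mol⁻¹). The mM to
mol m⁻³ conversion is the identity.

## Synthetic data

No measured single-cell dataset accompanies the model, so
`celltherm.synthetic_data` generates seeded fixtures: osteocyte-like
diameters log-uniform in 20–100 µm (a scale-free draw across the factor-5
size range), membrane thicknesses uniform in 5–10 nm, cell temperatures
Gaussian about 37.4 °C with a 0.1 K standard deviation, and ion
concentrations multiplied by mean-one lognormal factors of coefficient of
variation 0.05. These choices are fixtures, not biology: they emulate the
parameter ranges the model operates over, not real osteocyte morphology
distributions, measurement noise, or covariance between size and ionic
state. Passing tests on this population demonstrate numerical correctness
and sign consistency of the pipeline, not agreement with experimental cell
data. All randomness is a pure function of the seed and centralized in this
module; every scientific operation is deterministic.

`recover_calibration` is the matching parameter-recovery harness: with the
exponent fixed at −2 the fit is an intercept-only least squares on the log
scale, exact for noiseless data, with a delta-method standard error used by
the 3-SE recovery tests (n = 50 pairs, 5% multiplicative noise, fixed seed).

## Numerical choices

- The potential-split identity Δϕ_Na = Δϕ_Cl + Δϕ_K + Δϕ_Ca is enforced
  exactly by computing the last share as the residual.
- Zero denominators (mole balance), zero fields (flux inversion), empty
  permeability sets (GHK) and out-of-range temperatures (>400 K) are
  rejected with diagnostics naming the offending term or ion.
- Equality tests on algebraic identities use relative tolerances of 1e-10 to
  1e-12; log antisymmetry holds only to rounding of ln(a/b) vs −ln(b/a) and
  is checked at 1e-12 relative.
- The report and all generators are byte-deterministic for a fixed
  configuration and seed; problem sizes in the test suite (10⁴-draw moment
  checks, 10³ randomized balance states, 50-pair calibration fits) keep the
  full suite in a few seconds.

## Known limitations

- No channel gating kinetics, Hodgkin–Huxley dynamics, or Ca²⁺-extended GHK.
- No spatial heat conduction or transient thermal response; the balance is
  quasi-static.
- The wave-mechanics scale (membrane force/perturbation) and the resonance
  law are calibrated ansätze, as flagged above; computed potential
  perturbations must not be read as gating thresholds, and no exposure-safety
  dosimetry is implied.
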