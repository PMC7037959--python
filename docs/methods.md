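# Methods

This note documents the model equations, the choices made where the design
was open, the synthetic-input generators, and the numerical behavior of the
solvers. It states no result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Two-stage dilution

The plume is treated in two regimes. During the first second the exhaust
jet expands from the funnel cross-section `S0` as

    S(t) = (sqrt(S0) + t·σ_w)² − (t·α·V_S)²,
    σ_w² = (α·U)² + σ_wt² + (α·u_jet)²,

with `α = 0.1`, traffic turbulence `σ_wt = 0` (negligible for ship events),
and the jet velocity `u_jet` held equal to the stack exit velocity `V_S`
over the 1-s stage (no decay law is imposed). The dilution ratio is
`DR = S(1 s)/S0` and the plume temperature after the stage is
`T_P = T_A + (T_E − T_A)/DR`. Should the printed form of S(t) fall below
`S0` (pathological inputs), the area is floored at `S0` with a warning;
the subtraction can otherwise produce a shrinking plume, a regime the model
is not meant to describe.

**Stack preset.** The ROPAX ferry preset uses an exhaust-pipe cross-section
of 0.55 m² (diameter ≈ 0.84 m), exit velocity 25 m s⁻¹, and exhaust
temperature 580 K. With the fourteen events' winds (0.8–6.3 m s⁻¹) this
gives DR between 7.8 and 8.7 — "approximately eight" with no practical wind
sensitivity, because the jet term dominates the entrainment velocity.

**Coagulation during the expansion** is integrated as monodisperse
Smoluchowski loss, `dN/dt = −K·N²`, inside the analytically expanding
cross-section, with the concentration referred to the diluted end-of-stage
value and scaled by `U_ref/U` (a fixed source strength advected by weaker
wind produces a denser plume). The Fuchs self-kernel at the exhaust
count-median diameter (default 15 nm) is multiplied by a polydispersity
enhancement `kernel_scale = 4`: small–large pairs coagulate far faster than
equal pairs, and the factor represents scavenging across the real
multimodal spectrum. Typical events survive at 0.82–0.94; the weak-wind
event drops to ≈ 0.6–0.7. The corresponding dilution-only survival is
exactly 1/DR.

Beyond 1 s the centerline concentration of an inert tracer follows
`y(x) = a·x^−b`, fitted by ordinary least squares in log–log space
(points at x ≤ 0 or nonpositive background-subtracted concentrations are
dropped with a warning; at least three valid points required). The mixing
tendency applied to every plume scalar is `dN/dt = −(b/t)(N − N_BG)`. The
driver integrates this analytically per step — factor `((t+dt)/t)^−b` —
so mixing can never overshoot the background for any step size. The plume
depth grows as `H_P(t) = sqrt(H_P0² + (a'·(10⁻³·U·t)^b)²)` with
`H_P0 = 5.5 m` and `a'` ∈ {110.62, 86.49, 61.14} for unstable/neutral/
stable conditions.

**Stability and b per event.** The boundary-layer diagnosis of a full
dispersion model is out of scope; stability is assigned from wind speed and
time of day (U ≥ 4 m s⁻¹ in daytime → unstable; 2–4 → neutral; U < 2 or a
winter early morning → stable), and the dilution exponent by stability
(1.40 / 1.26 / 1.00), spanning the observed 0.99–1.47 range with the
observed mean for neutral conditions.

## Gas chemistry

A reduced scheme carries only what feeds the aerosol: SO3 hydration to
H2SO4 (pseudo-first-order, 5 s⁻¹, so > 99% of co-emitted SO3 converts
within ~1 s), SO2 + OH → H2SO4 (termolecular, k0 = 3.3·10⁻³¹(300/T)^4.3,
k∞ = 1.6·10⁻¹², F_c = 0.6), and the NO–NO2–O3 photostationary state solved
as a quadratic conserving NOx and total oxidant (j = 0 reduces to
titration). OH is prescribed: 3·10⁶ cm⁻³ in daytime plumes, 10⁴ cm⁻³ in
dark winter events. Organic vapors are chemically inert (emission +
dilution + condensation only). Gases are stored as molecules cm⁻³ with
µg m⁻³ converters. Sulfur is conserved exactly across SO2 + SO3 + H2SO4
by construction.

Initial diluted-plume concentrations (molecules cm⁻³): SO2 3·10¹², SO3
3·10¹⁰ (1% of SOx as SO3; 2% in scenario 2XSO3), NO 4·10¹², NO2 4.4·10¹¹
(90:10 NOx split), O3 equivalent to 10 µg m⁻³ (titrated plume core), C22H46
and C28H58 2·10¹¹ each, C34H70 3.3·10¹¹ — mid-points of the
emission-derived ranges for these vapors. Background: O3 60 µg m⁻³, small
NO/NO2/SO2.

## Nucleation

Binary homogeneous H2SO4–H2O nucleation uses the published polynomial
parameterization of the classical theory (critical-cluster mole fraction
and log-rate as cubic-in-T polynomials of ln RH and ln[H2SO4]), valid
190–305 K, 0.01–100% RH, 10⁴–10¹¹ cm⁻³, with J capped at 10¹⁰ cm⁻³ s⁻¹.
Above 305 K the polynomial is evaluated at its high-temperature edge
(smooth extrapolation accepted to 400 K, the warm-exhaust regime). The
critical-cluster size is derived from the rate fit itself via the first
nucleation theorem, `n_acid = ∂lnJ/∂ln[H2SO4]`, total molecules
`n_acid/x`, and the hydrated cluster volume from partial molecular volumes
— giving 1–1.5 nm clusters at plume conditions. Clusters are inserted into
the section containing the cluster diameter with dry composition H2SO4
(water is re-equilibrated diagnostically), consuming the corresponding
gas-phase acid.

The organic-involving variant (HET) multiplies the binary rate by
`1 + [org]/10¹¹` and assigns the cluster an organic mass share
`[org]/([org] + 10¹¹)` drawn from the C34 vapor; it reduces exactly to the
binary mechanism when no organic is present.

## Condensation (analytical predictor)

For each vapor the per-section uptake coefficient is
`k_i = 2π·D·d_i·N_i·β(Kn)` with the Fuchs–Sutugin transition correction
(accommodation 1). The new gas concentration solves the implicit balance
`C' = (C + Δt·Σ k_i·C_eq,i)/(1 + Δt·Σ k_i)`, and each section receives
`Δt·k_i·(C' − C_eq,i)`; evaporation is limited to the section's available
component mass and the gas is updated from the actually transferred sum, so
every species' gas + particle budget closes to machine precision.
Equilibrium concentrations include Raoult (mole fraction over the liquid
mixture, soot excluded) and Kelvin (`exp(4σv_m/kTd)`) factors. Saturation
pressures follow Clausius–Clapeyron anchored at 298 K: C22H46 10⁻⁵ Pa
(ΔH_vap 120 kJ mol⁻¹), C28H58 10⁻⁸ Pa (145), C34H70 10⁻¹² Pa (170);
H2SO4 is treated as involatile. The two semivolatile alkanes share the
SV-OM reservoir (split evenly for the mole-fraction bookkeeping); C34H70
maps to ELV-OM, H2SO4 to sulfate.

After condensation, sections whose mean particle volume has left their
bounds are rebinned: the content moves to the two sections bracketing the
mean volume with a split conserving both number and every component's mass.
This keeps number/mass consistency on the fixed grid while letting the
nucleation-size mode grow across sections.

## Coagulation (semi-implicit sectional)

The Fuchs transition-regime Brownian kernel is precomputed per temperature
(re-used within 1 K). Coalesced volume `v_i + v_j` is split between the two
bracketing fixed sections with number- and volume-conserving fractions; the
top section absorbs overflow volume. Component masses follow Jacobson-style
sequential semi-implicit updates (ascending sections, updated donors,
self-partition credited in the loss term), which conserves every
component's total mass to machine rounding and is unconditionally positive.
Number uses implicit loss with explicit pair gains (one particle per
event); against the constant-kernel monodisperse closed form
`N(t) = N0/(1 + ½KN0t)` the solver is accurate to ~10⁻⁶ relative at the
default step.

## Deposition, water, temperature

Dry deposition applies a first-order loss `v_d(Dp)/H_P(t)` per section with
a classical two-resistance smooth-surface velocity (settling + aerodynamic
resistance `ln(z/z0)/(κu*)` + surface uptake via Sc^−2/3 and impaction
10^(−3/St)); friction velocity defaults to 0.3 m s⁻¹, z = 10 m,
z0 = 10⁻³ m. Particle-bound water is diagnosed (not kinetic): per section,
water volume = Σ κ_c·V_c·a_w/(1 − a_w) with κ = 0.5 for sulfate, 0.05 for
the organics, 0.01 for NV-POM, 0 for soot, and a_w capped at 0.95. Plume
temperature is the event's ambient value; scenario T310K starts at 310 K
and relaxes to ambient with the dilution factor `((t+dt)/t)^−b` per step.

The driver advances chemistry → nucleation → condensation → coagulation →
deposition → dilution at Δt = 0.1 s from t0 = 1 s to 900 s, recording
snapshots every second; states are validated for negativity/NaN every 10 s
of model time and abort with a stage-labeled diagnostic. Halving Δt changes
end-of-run totals at the sub-percent level (operator-splitting error).

## Synthetic inputs

The generators emulate the statistical structure of the measured inputs,
not the measurements themselves:

* **Diluted exhaust**: three lognormal modes — nucleation (median 5.5 nm,
  GSD 1.35, composition 20:80 sulfate:NV-POM by dry mass; 100% sulfate in
  HSULF), intermediate nonvolatile (40 nm, GSD 1.5, soot+NV-POM), and
  accumulation (100 nm, GSD 1.6, soot-rich). Mode number fractions are
  solved so that 29% of total number lies below 25 nm; total number
  defaults to 10⁷ cm⁻³ (diluted exhaust is observed at 10⁶–10⁷ cm⁻³, and
  this puts the sub-25-nm mode near its observed ~3·10⁶ cm⁻³ mean). Only
  the mode peaks are observationally constrained; widths and the
  intermediate/accumulation compositions are package presets.
* **Urban background**: three modes normalized to 5400 cm⁻³ with a mixed
  sulfate/organic/soot composition typical of size-fractionated urban
  background measurements.
* **Dilution samples**: `a·x^−b` with multiplicative lognormal noise,
  seeded.
* **Population rasters**: multinomial scatter of hotspot totals over 100-m
  cells with Gaussian weights, seeded; totals are preserved exactly.

What passing tests on these inputs do **not** show: agreement with any
individual measured event (per-event emission rates and measured size
distributions are not reproduced), lateral in-plume heterogeneity, or
real building-level infiltration variability.

## Exposure stage

Ring value = mean trajectory UFP (Dp < 100 nm) concentration over each
40-m downwind interval, uniform across the ±15° sector, background
elsewhere and beyond 3.6 km; the centerline concentration is deliberately
inserted across the full sector width (this overstates the outer plume and
is the convention the exposure numbers assume). Daily means weight the
plume field by 5 min per scheduled passage (overlaps merged with a
warning). The ring-sector field is resampled to the 100-m population raster
by exact shapely polygon overlap. Exposure is restricted to the home
microenvironment with a flat time-at-home fraction of 0.6 (hourly
time-activity tables are not reproduced; the fraction is configurable) and
F_inf = 0.56. Excess risk is linear: 4% per 6250 cm⁻³ daily-mean UFP
increment, evaluated at the most-exposed populated cell.

## Diagnostics

`summarize` reports number below 25 nm (nucleation-size, "NP"), 25–100 nm,
total number, per-component dry mass and fractions for UFP and for NP, the
water mass fraction, and the interpolated peak diameter of the sub-4-nm
fresh mode where present. `growth_rate` fits the parabola-interpolated peak
diameter of the sub-15-nm spectrum against time over t = 30–900 s: the
first seconds are a vapor-burst regime in which all nucleation-size
particles grow almost discontinuously, while the fitted window captures the
slow vapor-limited growth phase that measured plume growth rates describe.

## Numerical sizes used in the tests

Full-length runs simulate 900 s at Δt = 0.1 s (≈ 9000 steps, ~25 s wall
time each); scenario comparisons use 35-s runs, which suffice for the 30-s
diagnostics. These sizes are the package's verification defaults and are
set in the test fixtures.

## Known limitations

* The exposure stage and the first-stage jet model are parameterizations;
  neither resolves in-plume turbulence or lateral concentration profiles.
* The high-temperature behavior of the nucleation parameterization above
  305 K is an extrapolation of the low-temperature fit; scenario T310K
  therefore probes the temperature relaxation, not an independent high-T
  nucleation data set.
* Semivolatile partitioning uses two surrogate n-alkanes with literature
  anchor pressures; absolute organic mass fractions carry that uncertainty.
* Stability classes and per-event dilution exponents come from a documented
  wind/time-of-day mapping rather than a boundary-layer model.
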