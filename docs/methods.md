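# Methods

## Model structure and assumptions

The model couples two pieces: equilibrium carbonate chemistry in the
plastid middle space, and a one-pool flux balance for plastid CO₂.

**Carbonate speciation.** The middle-space DIC pool is assumed to be at
chemical equilibrium at the local pH, with apparent dissociation
constants given by temperature/salinity polynomial fits (see README for
the formulas). Only the two carbonic-acid equilibria are modelled; the
borate and phosphate contributions to alkalinity, CO₂ fugacity, and
pressure corrections of full seawater CO₂-system solvers are out of
scope — the speciation question here is only what fraction of a given
DIC pool is CO₂(aq) at a given pH. Whether the underlying pK fits are
on a mol kg⁻¹-seawater or mol L⁻¹ concentration scale is immaterial to
the outputs: the speciation formula uses only the dimensionless ratios
K1/[H⁺] and K1·K2/[H⁺]², so the DIC unit (μmol L⁻¹ throughout)
propagates unchanged.

**Flux balance.** Plastid CO₂ is a single well-mixed pool fed by
passive diffusion from the middle space, D·([CO2]_m − [CO2]_p), and
drained by Michaelis–Menten fixation, Vmax·[CO2]_p/([CO2]_p + K).
Middle-space DIC (and hence [CO2]_m) is held constant: leakage of CO₂
back to the cytosol and depletion of the middle-space pool by net
uptake are not modelled, and no HCO₃⁻ transporter acts across the inner
membranes. Setting the derivative to zero yields
x² + (Vmax/D + K − [CO2]_m)·x − K·[CO2]_m = 0; the product of the roots
is −K·[CO2]_m < 0 whenever [CO2]_m > 0, so exactly one root is
non-negative and is the physical steady state.

## Parameters

| Parameter | Units | Default | Meaning |
|---|---|---|---|
| DIC_m | μmol L⁻¹ | 993 | middle-space dissolved inorganic carbon |
| pH_m (reference) | — | 7.59 | the one mean intracellular pH reported for a diatom |
| K | μmol L⁻¹ | 44 | half-saturation constant of CO₂ fixation |
| T | K | 298.15 | temperature driving the pK fits (CLI accepts °C) |
| S | — | 35 | practical salinity |
| Vmax/D | μmol L⁻¹ | grid 10⁻¹–10⁴ | uptake capacity relative to membrane diffusivity |

Temperature must be absolute: the ln T terms of the pK fits are valid
only in Kelvin. T = 298.15 K and S = 35 are the standard-seawater
defaults; with them the four reference middle-space CO₂ concentrations
(17, 64, 410, 870 μmol L⁻¹ at pH 7.59, 7, 6, 5) are reproduced to their
printed two-significant-figure precision, which is why they are the
package defaults. Time units are arbitrary — only Vmax/D (a
concentration) determines the steady state — so `KineticParams`
accepts either (Vmax, D) explicitly or the ratio with D normalized
to 1; both paths are tested for identical steady states.

The sweep's default Vmax/D grid is seven log-spaced values over
[10⁻¹, 10⁴] μmol L⁻¹. No canonical set of plotted Vmax/D values exists
to adopt, so the grid is chosen to straddle K = 44 μmol L⁻¹ by roughly
±2.5 decades, which carries the steady state from the uptake-limited to
the diffusion-limited regime; the analytic fold-change bounds are
reported alongside and do not depend on the grid. The default pH grid
is 5.0–8.0 in steps of 0.05, covering the four reference pH points
exactly; the reference pH (7.59) is inserted into any grid that lacks
it so fold changes normalize to exactly 1 there.

## Numerical choices

- **Root evaluation.** With b = Vmax/D + K − [CO2]_m the positive root
  is (−b + √(b² + 4·K·[CO2]_m))/2; for b > 0 the equivalent form
  2·K·[CO2]_m/(b + √·) is used to avoid catastrophic cancellation at
  large Vmax/D. Every solve also reports the quadratic residual at the
  returned root.
- **Degenerate cases.** D = 0 is answered explicitly (CO2_p = 0 if
  Vmax > 0, else CO2_p = [CO2]_m), never via division; Vmax = 0 gives
  CO2_p = [CO2]_m. A zero reference fixation rate makes the fold change
  undefined and is reported as NaN, not infinity.
- **ODE oracle.** The time integration of the balance equation exists
  as an independent check on the closed form, not as the production
  path. It uses an adaptive implicit scheme (Radau, rtol 1e−10) because
  the relaxation is stiff at large Vmax/D; the derivative at CO2_p = 0
  is non-negative whenever [CO2]_m ≥ 0, so trajectories stay
  non-negative. Convergence is declared when the terminal derivative
  falls below reltol·D·max(1, [CO2]_m) and is always reported.
- **Output formatting.** CSV numbers are written with 10 significant
  digits so identical configurations produce byte-identical files; each
  scan emits a JSON provenance sidecar recording every resolved
  parameter and the package version.

## Validation strategy

The test suite checks the closed-form steady state against the ODE
oracle over randomized draws spanning Vmax/D from 10⁻³ to 10⁵ μmol L⁻¹,
verifies the uptake- and diffusion-limited asymptotes at extreme
Vmax/D, and asserts the structural invariants: species conservation
(CO₂ + HCO₃⁻ + CO₃²⁻ = DIC to 1e−10 relative), monotone decrease of
CO₂(aq) with pH, linearity in DIC, flux balance
V_Cfix = D·([CO2]_m − [CO2]_p) at steady state, and the sandwich
low ≤ fold change ≤ high for every finite Vmax/D. Randomized property
tests are seeded/derandomized so runs are reproducible.

There is no synthetic-data generator in the usual sense: the model
consumes no measured data, only scalar parameters, and its reference
conditions (DIC 993 μmol L⁻¹, pH 7.59, K 44 μmol L⁻¹, standard
seawater T and S) are fixed as the defaults above. Passing tests
demonstrate internal consistency of the model and agreement with its
reference outputs at those conditions — not that the parameter values
describe any particular organism.

## Limitations

- Constant middle-space DIC: strong uptake at low pH would in reality
  deplete the pool unless resupplied; the model ignores this feedback.
- The middle-space pH is an input, not computed from proton-pump
  kinetics; the model answers "what if the pH were X", not "what pH
  does the pump achieve".
- Carbonic-anhydrase-catalysed interconversion kinetics are subsumed in
  the equilibrium assumption; if equilibration were slower than
  diffusion the speciation step would overestimate CO₂ supply.
- Alkalinization above the reference pH is represented only as grid
  points with fold change < 1; no separate mechanism is modelled.
- Single plastid pool: no gradient across the four individual
  membranes; D lumps them into one effective diffusivity.
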