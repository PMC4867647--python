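# Methods

`whcns` simulates a 1-D soil–crop column at a daily time step, coupling
surface hydrology, unsaturated water flow, heat transport, nitrogen
transport, organic matter turnover, and generic crop growth. This note
records the governing equations as implemented, the defaults and why they
were chosen, the numerical choices, and the limitations a user should know
before trusting an output.

All internal computation uses one unit system — length cm, time d,
temperature °C, solute concentration µg N cm⁻³ (per bulk soil volume where
stated), pressure head cm (negative unsaturated) — with conversions at the
file and API boundary (mm of water, kg ha⁻¹ of N and dry matter).

## Daily operator splitting

Each day applies, in order: (1) management events; (2) FAO-56
Penman–Monteith reference ET, scaled by the crop coefficient and split by
`1 − exp(−Ke·LAI)` into potential transpiration and potential soil
evaporation; (3) SCS curve-number runoff of daily rain, then Green-Ampt
capacity limiting of infiltration; (4) Richards-equation redistribution
with the root-uptake sink; (5) heat transport with the day's water fluxes;
(6) organic turnover and inorganic N transformations; (7)
convection–dispersion transport of urea-N, NH₄-N and NO₃-N with the
transformation and uptake terms as source/sink profiles; (8) crop
development and growth. Transformations precede solute transport because
they supply the CDE's source terms — the ordering within the day is a
modelling assumption, not a law; at a daily step the alternative ordering
differs at second order.

Only the Richards and CDE solvers sub-step within a day. The water
sub-loop starts at `dt_max` (1 d), halves the step whenever the Picard
iteration fails to converge, down to `dt_min` (0.1 d), and at `dt_min`
accepts a flagged step rather than aborting (heavy rain or basin irrigation
on dry sand is exactly when a simulator must not crash). The last
successful step size is carried to the next day as a warm start. Flagged
steps are counted in the ledger; runs reported here have ≤ ~10 per
two-year simulation and their mass-balance impact is accumulated and
reported, not hidden.

## Soil water

Retention and conductivity follow van Genuchten–Mualem
(θr, θs, α, n, Ks, ℓ = 0.5). The Richards equation is solved in mixed form
(Celia-style): the θ-update is written against the new-time water content
with the specific capacity only as a Picard preconditioner, so the
converged step conserves mass to the iteration tolerance (observed:
10⁻¹⁰–10⁻⁸ of storage per step). Time weighting is fully implicit —
the mixed form's exact balance requires the implicit θ update; a
Crank–Nicolson weighting of the flux terms would buy temporal accuracy the
daily forcing cannot use and give up unconditional smoothness. Two
stabilisations guard the nonlinear iteration: per-iteration head updates
are clamped to 500 cm, and a damping factor engages when the update stops
contracting. Neither changes the converged solution.

Internodal conductivity is the geometric mean. The top boundary is a flux
(infiltration − evaporation) that switches to a Dirichlet head when the
surface would pond (h = 0) or dry beyond `h_air_dry` (−10⁵ cm). The
evaporation flux is additionally bounded each sub-step by the Darcy rate
the profile can deliver toward an air-dry surface — without this limit the
surface node's head diverges and the Picard iteration stalls. Soil
evaporation below field capacity is reduced by
`exp(−shape·depletion)` (shape 3, configurable); the paper-family models
leave this sub-grid process open. The bottom boundary is free drainage
(unit gradient) by default — water tables at the target sites are tens of
metres down — or a prescribed head.

Runoff uses CN = 75 under AMC-II by default (curve numbers are site inputs,
and runoff is small in level-basin systems); the AMC-I/III conversions are
standard. The Green-Ampt wetting-front suction is the integral of relative
conductivity over suction (Neuman's approximation) unless overridden.

## Soil heat

Conduction–convection on the water grid, fully implicit with first-order
upwind convection — an M-matrix, so the discrete maximum principle holds.
Surface temperature is the daily air mean pulled toward a 10-day running
mean as canopy closes (`shade = 1 − exp(−0.2·LAI)`); the bottom boundary is
held at the driving series' long-term mean air temperature. Heat capacity
is a volumetric mixture of mineral, organic and water components; apparent
conductivity interpolates between dry and wet end members with √θ, spanning
0.2–1.8 W m⁻¹ K⁻¹. These are standard textbook mixtures; the step-change
test against the semi-infinite erfc solution agrees within 0.014 °C on a
1 cm grid.

## Solute transport

The retarded CDE for each species uses fully implicit first-order upwind
advection and implicit dispersion — unconditionally stable, monotone and
positivity-preserving, at the price of numerical diffusion `≈ v·Δz/2 +
v²·Δt/2`. The grid-refinement acceptance test quantifies this: against the
exact flux-inlet (Cauchy) front solution the peak error is 1.4% at
Δz = 0.5 cm and 0.57% at Δz = 0.25 cm. The hydrodynamic dispersion
coefficient is `D₀·τ + D_L·|q|/θ` with Millington–Quirk tortuosity
`τ = θ^(7/3)/θs²`; defaults D_L = 3 cm, D₀ = 2.4 (nitrate, urea) and
1.2 cm² d⁻¹ (ammonium). Boundaries are third-type: solute enters only with
infiltrating water (fertigation sets the inflow concentration), and leaves
with bottom drainage (leaching).

Adsorption is a generalized isotherm `s = Kd·c^β`, linear by default with
Kd = 1 cm³ g⁻¹ for ammonium only; nitrate and urea travel unadsorbed.
Nonlinear β is solved by inner Picard/Newton iterations.

The transformation terms are daily rates evaluated on day-start stocks and
applied inside the CDE. Because transport moves mass within the day, a
node's prescribed sink can overrun its remaining stock at a sharp advected
front; each sub-step therefore caps the net sink at 90% of the node's
current stock. The capped amount is decomposed by the node's sink
composition and reconciled: the uptake share reduces the crop's N credit,
the volatilization and denitrification shares reduce those ledger tallies,
and a capped nitrification (or urea hydrolysis) also withdraws the
corresponding source from the downstream species within the same sub-step.
Only the immobilization share cannot be handed back (the pools are already
updated); it is reported in the ledger as `n_unapplied` — typically
0.01–0.06 kg N ha⁻¹ over a two-year rotation against ~400 kg ha⁻¹ of
inputs, and it is the entire nitrogen closure residual.

Fertilizer placement: `surface` mixes into the top 1 cm, `deep` into a
5–10 cm band, `mix` through the plough layer (20 cm), `fertigation`
dissolves the dose in the day's irrigation water. Manure and straw enter
the added-organic-matter pools at their C/N ratio.

## Carbon and nitrogen turnover

Six pools (SOM1/2, SMB1/2, AOM1/2) decay by first-order kinetics with
standard-condition coefficients multiplied by abiotic modifiers:
temperature (0 at ≤0 °C, linear to 1 at 20 °C), moisture (piecewise in pF,
optimum pF 1.5–2.5, 0.6 when saturated, 0 at pF 6.5), and clay protection
for native SOM (linear, floor 0.2). Routing: AOM1→SMB1, AOM2→SMB2,
SOM1/2→SMB1 at utilisation efficiency 0.6 (remainder respired as CO₂);
microbial death (the d* share of the SMB rate) transfers to SOM2 without
respiration loss, maintenance respires fully. Rate defaults
(`n_transformation_defaults.yaml`) are the DAISY-style values: SOM1
2.7·10⁻⁶, SOM2 1.4·10⁻⁴, SMB1 d*+m* = 1.985·10⁻³, SMB2 2·10⁻²,
AOM1 5·10⁻³, AOM2 5·10⁻² d⁻¹; C/N 6.7 (SMB) and 11 (SOM). Within-step
decay is exponential (`C·(1−e^(−kΔt))`), so pure decay is exact regardless
of step size.

Net mineralization follows from the C/N bookkeeping of every flux; when
negative (immobilization) and the demand exceeds available mineral N, the
whole step is scaled down proportionally per node. Mineralized N is
credited to NH₄. Carbon is conserved identically (ΔΣC + CO₂ = inputs,
tested to 10⁻¹⁰ relative).

Inorganic transformations (daily, confined to the microbially active
0–30 cm except where noted):

- **Urea hydrolysis** — first order, rate `K_urea·WFPS` (K_urea 0.4 d⁻¹,
  WFPS = θ/θs); applied over the whole profile since urease is ubiquitous.
- **Ammonia volatilization** — `k_vol · f_NH₃(pH, T) · f(z) · N_am`, where
  f_NH₃ is the equilibrium NH₃ fraction from the temperature-dependent pKa
  (0.09018 + 2729.92/T_K) — this supplies the pH- and
  temperature-monotonicity the Freney approach requires — and f(z) falls
  linearly to zero at 10 cm depth. k_vol = 2 d⁻¹ gives ~10%/d losses from
  surface ammonium at pH 8, a realistic calcareous-soil magnitude.
- **Nitrification** — Michaelis–Menten `Vn*·N/(Kn+N)` with Vn* = 5
  µg cm⁻³ d⁻¹ and Kn = 50 µg cm⁻³, times temperature (optimum plateau
  25–35 °C) and moisture (oxygen-limited near saturation) modifiers.
- **Denitrification** — potential rate `α_d·S_CO₂` (α_d = 0.1 g gas-N per g
  CO₂-C) capped by `K_d·N_NO₃` (K_d = 0.1 d⁻¹), throttled by an
  anaerobiosis factor that is zero below WFPS 0.7 and rises quadratically
  to 1 at saturation.

Simultaneous sinks on one pool are allocated sequentially — volatilization,
nitrification, crop uptake, immobilization, denitrification — each against
remaining availability with a 5% safety margin, so no substrate is ever
overdrawn.

## Crop growth

Development is thermal time above Tbase in two phases: sowing→emergence
(requirement `a + b·depth`, defaults 50 + 10/cm) and emergence→maturity
(Tsum, e.g. 2110 °C·d for winter wheat). Overwintering crops go dormant
after five consecutive sub-zero days and resume after five above zero;
dormancy freezes development, root growth and assimilation.

Gross canopy assimilation integrates the saturating leaf response
`AMAX·(1−exp(−ε·I/AMAX))` over the exponential canopy light profile
(5-point Gauss), with ε = 120 kg CO₂ ha⁻¹ h⁻¹ per MJ m⁻² h⁻¹ absorbed
PAR — the PAR quantum-yield scale (≈12 g CO₂ per MJ absorbed PAR), so top
leaves in full sun are light-saturated and deep leaves light-limited. The
product is scaled by `min(cf_w, cf_N)` (a product rule is selectable),
converted CO₂→CH₂O, charged temperature-dependent maintenance (Q10 = 2;
coefficients 0.03/0.015/0.01/0.01 d⁻¹ for leaf/stem/root/storage) and
growth respiration (Yg = 0.7), and partitioned to organs by a
stage-indexed piecewise-linear table (shipped defaults are calibration
starting points, not site truths). LAI is leaf mass × SLA, with SLA
declining linearly from SLA_max to SLA_min over development. Yield is the
storage-organ mass at maturity — direct accumulation, no harvest index. At
harvest, roots return to the AOM pools with their proportional N share;
everything else is exported.

Root depth follows a Verhulst logistic anchored exactly at
(tR_min, xR_min) and (tR_med, xR_med) with asymptote xR_max, capped at
R_max. Root density is triangular to the rooting front. Water uptake uses
the Feddes pressure-head response (defaults −1/−25/−600/−15000 cm; a
salinity response hook exists and is neutral) with compensation: the
weighted stress index ω = ∫a_w·b dz is compared with the critical value
ω_c (default 0.5); at or above it, full demand is met by shifting uptake
toward unstressed nodes, below it transpiration is reduced to (ω/ω_c)·Tp.
cf_w = Ta/Tp.

Nitrogen demand is the deficit to the critical concentration from a
CERES-style exponential dilution curve (4.5% at emergence → 1.0% at
maturity, shape 3; minimum = 0.5 × critical), capped at a maximum daily
uptake (6–8 kg N ha⁻¹ d⁻¹ by crop). Uptake is min(demand, root-zone
mineral N), split between NH₄ and NO₃ in proportion to availability and
distributed over nodes by root density × concentration. cf_N is the
clamped linear CERES stress index. Seedling N at emergence is booked as an
external (seed) input to keep the ledger exact.

## Mass ledgers

The engine keeps cumulative water (mm), N and C (kg ha⁻¹) ledgers and
reports closure against stock changes. In the shipped two-year rotation:
water residual below 10⁻⁵ of inputs, carbon exact to rounding, nitrogen
≤0.02% (entirely the `n_unapplied` diagnostic above). The per-step
Richards mass error is accumulated separately (`water_solver_error`).

## Synthetic weather

The generator is deterministic in its seed: sinusoidal annual temperature
(default mean 9 °C, amplitude 11 °C, coldest mid-January) with AR(1)
anomalies; Bernoulli rain occurrence weighted toward summer with
exponential amounts (default 550 mm yr⁻¹ — a continental, summer-dominant
regime); radiation as a seasonal clear-sky envelope scaled by cloudiness
tied to rain; humidity and wind from clipped normal/gamma draws. It
emulates the marginal statistics and seasonality of a temperate continental
station, not multi-day synoptic persistence, frontal structure, or
radiation–temperature coherence — so passing conservation and lifecycle
tests under it demonstrates numerical and structural correctness, not
predictive skill on real sites. No real-site statistics are claimed.

## Problem sizes used in tests and the acceptance run

Conservation: the packaged two-year maize/winter-wheat rotation, 150 cm
profile at 5 cm spacing (732 days). Solver oracles: 300 cm columns at
1–5 cm spacing; the transport oracle at 0.25 cm and Δt = 0.002 d.
Sensitivity: one fertilized, irrigated maize season (March–October, 90 cm
profile), 18 parameters × ±10% = 37 runs; outputs are period-mean soil
water, NO₃, NH₄ (0–90 cm), mean LAI, final dry matter, yield. In that scan
the pore-size index n and saturated water content θs produce the largest
soil-water responses, consistent with the model family's known behaviour.

## Known limitations

- No macropore/preferential flow, snow, freeze–thaw latent heat, or
  surface energy balance.
- First-order upwind advection smears sharp solute fronts on coarse grids;
  use ≤1 cm spacing for breakthrough-curve work.
- The crop module is generic: no photoperiod or vernalization beyond
  thermal time, no pests/diseases, no phosphorus; partition tables and
  dilution-curve coefficients must be calibrated per site and cultivar.
- N₂O/N₂ partitioning of denitrified gas, CH₄, DOC and DON are out of
  scope; denitrified N leaves the budget as total gas-N.
- Long-term SOC trajectories are not a target; native pool rates are slow
  and effectively fixed over one or two seasons.
- The furrow/trickle irrigation methods are 1-D surrogates (wetted-fraction
  multipliers); lateral redistribution is not represented.
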