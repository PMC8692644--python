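# Methods

## Scope and model structure

`polarfoodweb` simulates a seasonally ice-covered shelf-sea ecosystem as a
nitrogen-currency flux network over functional guilds, coupled to a
sea-ice biogeochemistry layer and a fishing-fleet forcing layer. The domain
is an idealised Barents-Sea-scale box model: an inshore zone with one water
layer, an offshore zone with an upper (0–60 m, euphotic) and a lower
(disphotic) layer, and four sediment classes (rock, fine, medium, coarse)
under each zone — eight seabed habitats. Default geometry: total surface
area 1.60898 × 10⁶ km², inshore fraction 0.25, inshore depth 50 m, offshore
total depth 200 m.

The state is a flat vector of 75 pools (areal densities, mMN per m² of
total domain surface): water-column nitrate, ammonia, suspended
detritus+bacteria and phytoplankton per zone/layer; snow and ice nitrate
and ammonia, ice algae and ice detritus per zone; labile and refractory
sediment detritus and porewater nitrate/ammonia per habitat; macrophytes
and debris; corpses; fishery discards; omnivorous and carnivorous
zooplankton; four larval pools; suspension/deposit and carnivore/scavenge
benthos; planktivorous, migratory and demersal fish; seabirds, pinnipeds,
cetaceans and maritime mammals (polar bears).

## Flux-matrix formulation and conservation

The daily derivative is assembled as a pool-to-pool flux matrix `F`
(`F[i, j]` = flux from pool *i* to pool *j*), an input matrix (boundary
ocean inflow, rivers, atmospheric deposition) and an export matrix
(boundary outflow, sediment denitrification, burial of refractory detritus,
fishery landings). The state derivative is column sums minus row sums plus
inputs minus exports, so the domain nitrogen budget closes identically:
any flux that is scaled or limited affects donor and receiver by the same
amount. The test suite asserts annual closure to 1 × 10⁻⁸ relative;
observed residuals are at machine precision (~10⁻¹⁴ relative).

State is held as areal mass rather than concentration so that the budget
is an exact vector sum; rate laws convert to concentration internally
(layer volume per unit domain area). Reported state follows the same areal
convention (mMN m⁻²).

## Process formulations

**Primary production.** Multiplicative light × nutrient × Q10 saturation:
uptake = B·u_max·(E/(E+h_E))·S·Q10^((T−T_ref)/10) with
S = (w_NH4 + w_NO3)/(w_NH4 + w_NO3 + h_N), where w_NH4 = [NH4] and
w_NO3 = [NO3]·exp(−ψ[NH4]) — ammonia is taken preferentially and inhibits
nitrate uptake exponentially. Layer-mean irradiance comes from the
under-ice irradiance attenuated by water (k = k_w + k_SPM·SPM) averaged
over the layer. There is no production in the disphotic layer. Defaults:
u_max 0.545 d⁻¹ at T_ref 5 °C, Q10 1.5, h_E 8 E m⁻² d⁻¹, h_N 1 mMN m⁻³.

**Feeding.** Every consumer uses a preference-weighted Holling type-II
response: total uptake U = B_c·u_max·A/(A+h) with A = Σπ_i·max(P_i − r_i, 0),
apportioned across prey in proportion to their weighted availability. The
r_i are small prey *refuge densities* (spatial/behavioural refugia) that
make a residual of each pool invisible to predators; they bound prey
crashes and prevent numerical extinction under daily explicit stepping.
Ingested mass is split into assimilated (to the consumer), defecated (to
suspended detritus for pelagic/top consumers, labile sediment detritus for
benthos) and excreted (to ammonia / porewater ammonia) fractions summing
to 1. The predator→prey adjacency and weights are configuration, not code.

The three fish guilds are parameterised as near-satiated feeders (small
half-saturation): their per-capita energy intake is then almost independent
of prey density, and population regulation comes from a quadratic
(density-dependent) mortality term. This choice makes the equilibrium
biomass respond linearly to fishing mortality — a logistic surplus
production curve — which is what places the maximum of the demersal yield
curve at ~2.5 × the baseline harvest rate with B_MSY ≈ 0.55 B₀, consistent
with the assessment-derived reference points of the study region.

**Mortality.** Linear plus quadratic background mortality per consumer,
routed to corpses (fish, benthos, megafauna) or detritus (plankton,
larvae). Corpses settle and mineralise into labile sediment detritus and
are scavengeable.

**Migration.** Migratory fish, seabirds and cetaceans follow a monthly
presence schedule (fraction of the population inside the domain).
Presence scales feeding, predation exposure, mortality and harvest alike,
so an absent guild's state is frozen — it is neither eating nor eaten
while outside the domain.

**Ice dependence of megafauna.** Seabirds and cetaceans are entrapment-
limited: their feeding multiplier declines linearly from 1 in open water
to a floor under full cover. Pinnipeds are ice-edge dependent: the
multiplier is 1 up to a cover optimum (0.5) and declines Gaussian-wise to
a floor under consolidated ice. Polar bears hunt pinnipeds only on ice of
sufficient thickness: the hunting weight ramps linearly from 0 at 0.2 m to
1 at 0.8 m (cover-weighted mean thickness), and the complement is applied
to land-based scavenging on corpses, discards and birds.

**Sympagic biogeochemistry.** Ice cover, thickness and snow depth are
prescribed by forcing; there is no ice thermodynamics. Ice algae grow on
ice nitrate/ammonia (ammonia preferred) under mid-ice irradiance computed
through snow and half the ice thickness, and die to ice detritus; these
transfers conserve total ice nitrogen. Melt (prescribed volume loss)
delivers a proportional share of every ice-carried pool to surface water:
algae enter as phytoplankton, ice detritus as suspended detritus, nutrients
as their dissolved counterparts; snow pools melt with snow volume. Freezing
entrains dissolved nutrients — and a small phytoplankton inoculum for the
algae — from surface water in proportion to new ice volume. Atmospheric
deposition lands on open water (to nitrate) or on the ice sheet (to snow
nitrate) according to cover. Snow pools have no internal biology: they are
passive stores released on melt.

**Nitrogen cycle.** First-order, Q10-scaled mineralization of suspended
detritus to ammonia; nitrification of ammonia to nitrate in the water
column and porewaters; sinking of phytoplankton and detritus through the
layers into labile sediment detritus (distributed over the non-rock
habitats of each zone); labile→refractory transfer; slow refractory
mineralization plus permanent burial (export); porewater denitrification
(export); first-order porewater release to the overlying water.

**Transport.** Vertical mixing across the 60 m offshore interface scales
with the forced diffusivity (exchange velocity K/Δz over the mid-layer
distance); inshore–offshore exchange is a constant volume-exchange
velocity; both are implemented as symmetric concentration-based exchanges.
Gross ocean boundary in/outflow spans both offshore layers
(volume-proportional) with prescribed boundary DIN, detritus and
phytoplankton concentrations; rivers enter the inshore zone.

## Integration and spin-up

Fixed-step daily forward Euler (configurable substeps, default 1) with
per-pool donor-mass flux limiting: if a pool's total outgoing flux would
exceed 90 % of its mass in a step, all its outgoing fluxes are scaled down
proportionally, which preserves exact conservation and non-negativity.
The model is spun up under repeating 365-day forcing until the annual
cycle repeats: the convergence metric is the maximum over pools of the
relative change in annual-mean mass between successive years (pools below
10⁻⁹ mMN m⁻² excluded), with default tolerance 10⁻⁴ and a 200-year cap.
The shipped baseline converges in ~90–120 years and the converged cycle is
independent of initial conditions (two random starts agree to ~10⁻⁴
relative when spun to tolerance 10⁻⁵).

## Synthetic forcing

Monthly climatological cycles are sinusoid + offset parameterisations of a
present-day ("baseline") and mid-century ("future") polar shelf
climatology: winter-peaked ice cover/thickness/snow, a polar spring-summer
irradiance pulse, winter-peaked vertical mixing, seasonal boundary DIN.
The boundary DIN cycle is rescaled analytically so the annual integrated
boundary influx equals 8870 mMN m⁻² y⁻¹ (baseline) or 7855 mMN m⁻² y⁻¹
(future) exactly. The gross ocean exchange is ~2 % of domain volume per
day, chosen so that this influx is consistent with realistic boundary DIN
concentrations (~5–8 mMN m⁻³). The future preset scales ice to 35 % of
baseline, warms every temperature cycle by 1.5 °C and reduces the DIN
influx by the printed ratio. Daily values are piecewise-linear
interpolations between month midpoints with a circular December→January
wrap, on a 365-day year.

What the generator does **not** emulate: interannual variability, weather,
storm-driven mixing events, spatial structure within zones, and any change
in wave height, SPM, river or atmospheric inputs between scenarios. Tests
passing against this forcing therefore demonstrate internal consistency of
the model and its experiment machinery under idealised repeating
climatologies, not skill against observations.

## Fishing fleet

Eight gears (pelagic/demersal trawl, longline, gillnet, shrimp trawl,
creel, whaler, sealer) with relative effort shares (renormalised to 1),
per-guild harvest-rate weights (daily fishing mortality at unit effort),
discard fractions, bird/pinniped/cetacean bycatch rates and a seabed
abrasion rate with a sediment-class footprint. Gross catch of a guild is
Σ effort·rate·multiplier·biomass; discards enter the discard pool, an
offal fraction (5 %) of landed weight enters corpses, the remainder leaves
the domain as landings (a ledger export). Bycatch mass goes to corpses and
abraded benthos to labile sediment detritus. The two scenario multipliers
scale planktivorous and demersal rates only; bycatch, discard rates and
abrasion are held at baseline across all experiment runs. Migratory-fish
catch scales with presence.

## Experiments

**Scenario comparison** runs baseline and future climatologies to steady
state with identical fleets and reports per-pool percent change in annual
mean mass plus annual net primary production (NPP = water-column
phytoplankton uptake of DIN plus ice-algal uptake, read directly off the
flux matrix).

**Fishing sensitivity** re-runs the steady state over a multiplier grid
(default 0–3.5 in steps of 0.25, warm-starting each point from the
previous one), holding the other guild's multiplier at 1. MSY and F_MSY
are taken from the grid maximum refined by a quadratic fit through its
three-point neighbourhood; B_MSY is interpolated at F_MSY; status ratios
are computed against the multiplier-1 point. A maximum on the grid edge is
flagged and warned about rather than refined.

## Calibration and uncertainty

The objective is a Gaussian independent-error log-likelihood
Σ −½((model−obs)/sd)² over a target table of annual quantities. Simulated
annealing proposes one coordinate per iteration, uniform within a
step-scaled box clipped to bounds, with Metropolis acceptance and
geometric cooling every `cooling_interval` iterations; the best-ever
vector is returned. Likelihood-weighted Monte Carlo credible intervals use
weights ∝ exp(logL − max logL) and weighted empirical quantiles (defaults
0.005, 0.25, 0.5, 0.75, 0.995). The parameter-recovery experiment
regenerates targets from a run at known parameters, perturbs them with 5 %
multiplicative noise, and anneals a 4-parameter subset from a random
start; at desk scale (100 iterations, 15-year warm-started re-runs) the
median relative recovery error is below 20 %.

## Calibration of the shipped defaults

Process parameters were tuned (coordinate-wise, guided by per-pool annual
gain/loss budgets at equilibrium) so the baseline steady state reproduces
the headline annual quantities of the Barents-Sea study region: annual NPP
~870 vs 844.5 mMN m⁻² y⁻¹ reported; planktivorous/demersal annual-mean
biomasses ~3.5/6.8 vs 3.34/7.14 mMN m⁻²; annual landings ~0.174/0.304 vs
0.175/0.341 mMN m⁻² y⁻¹; demersal reference points F₀/F_MSY ≈ 0.41 and
B₀/B_MSY ≈ 1.6. The future run increases NPP by ~12 % (reported: 8 %),
driven by reduced ice shading, despite the smaller nutrient influx.

## Known limitations

- The planktivorous yield curve peaks near 2.9 × the baseline rate, well
  above the ~1.3 × suggested by assessments: megafauna predator-release
  adds surplus-production compensation that a different predation closure
  would avoid. Demersal reference points are matched closely.
- Refractory sediment detritus is given a decadal (not centennial)
  turnover so the spin-up equilibrates within the 200-year cap; its
  dynamics (burial versus slow mineralization) are otherwise unvalidated.
- Macrophyte growth is a light-limited logistic with debris shedding; its
  drivers are a design choice, not a validated formulation.
- Daily forward Euler with donor limiting is diffusion-limited in accuracy
  during the spring bloom; sub-daily substeps are available in
  configuration where sharper dynamics are needed.
- Problem sizes used in the shipped tests and in `scripts/acceptance.py`
  (steady-state spin-ups of one or two centuries, 15-point multiplier
  grids, 100-iteration annealing at 15-year re-runs) are the package's
  desk-scale defaults; all are configurable upward.
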