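# Methods

## Problem and overall design

The package estimates how a housing stock modifies exposure to air
pollution: outdoor-sourced PM2.5 and NO2 infiltrate dwellings attenuated by
envelope penetration, ventilation and surface deposition, while indoor
combustion (heating, gas cooking, smoking) adds CO on top of the outdoor
background. Exposure is summarised per dwelling as the occupancy-weighted
annual indoor/outdoor (I/O) concentration ratio (PM2.5, NO2) and as the
annual maximum 8-hour mean CO per room, compared against the WHO 8.1 ppm
8-h guideline.

Simulating every dwelling of a large stock directly is infeasible, so the
pipeline follows a metamodelling design: a fast multizone mass-balance
simulator generates training data at Latin-Hypercube-designed parameter
points per archetype, feed-forward surrogates learn the parameter → metric
map, and the surrogates are applied across the whole (synthetic) EPC-like
stock — once for the current stock and once for a whole-stock retrofit
scenario — before joining outdoor-pollution grids and smoking prevalence
and computing distribution summaries.

All inputs are synthetic. The generators are first-class, tested code that
emulate the statistical structure the analysis needs (stock composition,
postcode/grid/authority geography, smooth outdoor pollution surfaces,
seasonal-diurnal weather); passing tests therefore demonstrate internal
consistency and directional behaviour of the method, not calibration
against measured indoor concentrations or any real register.

## The multizone simulator

Four zones (kitchen 10%, living 25%, bedroom 20%, rest 45% of dwelling
volume; layouts fixed per archetype) exchange air with outdoors at the
dwelling air change rate λ, with each other through a common mixing node at
β = 0.5 h⁻¹ (each zone's exchange with the volume-weighted dwelling mean —
mass-conserving by construction), and lose pollutant to surfaces at
k = v_d · (S/V). Per zone i:

    dC_i/dt = P·λ·C_out + β·(C_mix − C_i) − (λ + k + f_i)·C_i + (1−w)·E_i/V_i

with P the envelope penetration factor, f_i any supplemental extract
ventilation (the kitchen fan, 0.06 m³ s⁻¹ during cooking), E_i scheduled
emission (mg min⁻¹) and w the fraction vented at source (90% for heating
appliances).

Pollutant conventions: PM2.5 v_d = 2.26×10⁻⁵ m s⁻¹ (deposition rate
0.19 h⁻¹ at the English-stock S/V of 2.3 m⁻¹; the unrounded ratio 2.335 m⁻¹
reproduces the printed velocities exactly and both are supported),
P = 0.8 in the September–May heating season and 1 in summer; NO2
v_d = 1.04×10⁻⁴ m s⁻¹ (0.87 h⁻¹), P = 1; CO v_d = 0, P = 1, reported in ppm
via mg m⁻³ × 24.45/28.01 (25 °C, 1 atm). Time steps: 10 min (PM2.5, NO2),
5 min (CO).

**Ventilation.** Infiltration uses the divide-by-20 engineering rule on the
50 Pa leakage rate: ach50 = q50·A_env/V, natural infiltration =
shelter × ach50/20 × sqrt[(u/u_ref)² + s²·|T_in − T_out|], i.e. wind and
stack terms superposed in quadrature, with terrain shelter factors city
0.7 / urban 0.85 / rural 1.0, reference wind u_ref = 4 m s⁻¹ and stack
coefficient s = 0.1 K^-1/2. Open windows add a fixed 4 h⁻¹. These constants
are standard engineering approximations chosen once to reproduce the
qualitative dependencies (wind, terrain, permeability, buoyancy); they are
all overridable. Envelope areas come from a box approximation (square
footprint, storeys and exposed-surface fractions per archetype); glazing
ratio is carried as a stock descriptor and surrogate input but does not
enter the ventilation model (the window bonus is fixed), so its fitted
effect is null by construction.

**Thermal model and occupant rules.** Indoor temperature follows a lumped
first-order relaxation to outdoor temperature (time constant 20 h) plus
free gains (0.15 °C h⁻¹), clamped at the 22 °C thermostat setpoint during
heating hours (06:00–08:00, 16:00–24:00) in September–May. Windows open
when daytime (07:00–22:00) indoor temperature exceeds 23 °C or night-time
exceeds 21 °C; the rule is applied dwelling-wide, year-round (during winter
heated night hours at exactly 22 °C this yields short purge-ventilation
openings). Thermal parameters are shared across the stock, so the indoor
temperature, heating-demand and window series are computed once per run.
Heating-emission sources are active only under heating demand (the
thermostat clamp engaged).

**Integration.** Backward Euler on the loss terms with the interzonal
coupling explicit at the previous sub-step: unconditionally stable,
non-negativity-preserving, and its fixed point under constant forcing is
exactly the ODE steady state P·λ·C_out/(λ+k) — the closed form used as the
simulation oracle. Halving the sub-step changes annual metrics by ≪ 0.5%.
The engine is vectorised over dwellings sharing an archetype (a year of
2000 dwellings ≈ 5–12 s), which is what makes 2000-point training designs
and 5000-dwelling direct-simulation checks affordable on one CPU.

## Designs and surrogates

Per archetype, a Latin Hypercube design stratifies q50 ∈ [0.5, 30] (the low
end covers post-retrofit permeabilities), floor area [25, 350] m², ceiling
height [2.2, 3.0] m, glazing [0.1, 0.4] and terrain (stock proportions).
The CO design adds a truncated-power-law heating emission rate
([0.5, 3000] mg min⁻¹, exponent 1.9 — spanning gas boilers to solid-fuel
stoves with the heavy tail a domestic-emission inventory shows), a
two-level cooking rate {0, 29} mg min⁻¹ and a smoking flag. Default design
size 2000 per archetype.

Surrogates are scikit-learn pipelines (standardiser + MLP). I/O models:
two 64-unit hidden layers, Adam with early stopping; predictions clipped to
[0, 1.05]. CO models: targets fitted as log1p (three decades of source
strength), with heating rate, floor area and q50 entering as log1p features
(the response is multiplicative in them), trained full-batch with L-BFGS
(128, 64 units) — on these smooth, low-dimensional responses quasi-Newton
training proved both more accurate and faster than SGD with early stopping,
which is why the CO models deviate from the early-stopping default.
Holdout quality (20% split) is recorded in every model artifact: I/O R²
and RMSE on the natural scale; CO additionally on the log scale, where
errors are homoscedastic — on the ppm scale a handful of extreme solid-fuel
points dominate the variance and make R² an unstable estimator.

Smoking and non-smoking variants are separate surrogate calls with the
smoking input toggled; eight independent models per metric mirror the
archetype structure.

## Stock parameterisation and retrofit

Certificate records are deduplicated to the latest inspection per building
reference (ties broken deterministically by full-row sort), records missing
required fields dropped and counted. Missing permeabilities are filled by a
simplified age-band scheme standing in for the full SAP procedure: base
infiltration 1.0 / 0.7 / 0.5 h⁻¹ (pre-1930 / 1930–1995 / post-1995), +0.1
for a solid-fuel flue, +0.05 for pre-1930 suspended floors, converted
through ach = q50·A_env/V/20. The retrofit scenario lowers fabric U-values
to age/fabric minima and subtracts ach reductions (draught-stripping 0.10,
floor sealing 0.05, cavity insulation 0.10, solid-wall 0.15, loft 0.05 h⁻¹
where applicable), floored at 0.1 h⁻¹, then re-derives q50. Retrofitted
records carry a flag and are returned unchanged on re-application, making
the operation idempotent. The reduction values are configurable stand-ins;
the published procedure cites external estimates without printing them.

CO emission configuration by fuel (mg min⁻¹, heating 90% vented): mains gas
15.9, LPG/propane 8.7, heating oil 1.7, solid fuel 2889, electric/community
none; gas cooking 29 (07:40–08:00, 19:00–19:30, with extract fan) only for
mains-gas dwellings, electric stoves otherwise; smoking 7.2 for 5 min per
hour, 08:00–22:00, unvented.

## Assembly and summaries

Indoor concentration of an outdoor pollutant = I/O × the dwelling's grid
cell value (outdoor is constant in time by design, so the ratio-of-means
and means-of-ratio definitions coincide). Total CO = indoor-source max 8-h
+ outdoor max 8-h — an upper bound, since the two windows need not
coincide. Smoking weighting duplicates each dwelling fractionally (weights
p and 1−p from its local authority) rather than randomly assigning smokers,
removing Monte-Carlo noise at equal expectation. Summaries are weighted
medians and 1st–99th percentile intervals using plotting positions that
reduce exactly to numpy's linear interpolation at equal weights, plus the
weighted fraction strictly above 8.1 ppm. Spatial correlation is Pearson's
ρ between postcode-mean indoor and cell outdoor values after merging
postcodes that share a grid cell (dwelling-weighted), which removes the
duplicated-outdoor multicollinearity.

## Problem sizes and numerical choices

Default run: 5000 dwellings, ~700 postcodes on a 30×30 grid, 30 local
authorities (smoking prevalence 10–25%), 2000-point designs per archetype,
full 8760-h years at 5/10-min sub-steps, one-week burn-in before metric
accumulation. A complete pipeline (training included) takes ≈ 4 min on one
CPU. All randomness flows from one user seed through fixed offsets; a run
is byte-reproducible given its seed.

Degenerate inputs are rejected loudly (negative concentrations, zero
outdoor means, empty grids, zero-variance correlations, proportions not
summing to one); WHO exceedance uses strict inequality at 8.1 ppm;
duplicate-date deduplication, quantile interpolation and one-hot encodings
are deterministic with documented tie-breaks.

## Known limitations

- The simulator is a lumped desk-scale model, not a pressure-network
  building-physics code: no solar gains, humidity, HVAC beyond the
  thermostat abstraction, or per-zone window behaviour.
- Synthetic stock distributions bracket English-stock survey ranges but are
  not calibrated to any survey; absolute concentrations are demonstrative.
  Directional results (NO2 I/O < PM2.5 I/O; retrofit raising indoor CO) are
  the supported claims.
- Outdoor concentrations are annual constants; seasonal covariation between
  outdoor levels and ventilation behaviour is not represented.
- The CO total is a theoretical maximum (window alignment ignored), and
  occupants are assumed home all day — both choices overstate exposure.
- On the synthetic stock the kitchen CO distribution is strongly bimodal
  (gas-type kitchens well below 8.1 ppm, solid-fuel kitchens far above), so
  the kitchen exceedance fraction can be identical before and after
  retrofit even though every kitchen's concentration rises; the living-room
  fraction does increase. With a real stock's wider spread both fractions
  would be expected to move.
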