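# Methods

## Model structure and assumptions

The model is a five-pool ordinary-differential-equation box model of one
hectare of forest: two tree biomass carbon pools (N-fixer `B_F`, non-fixer
`B_0`), two soil nitrogen pools (plant-unavailable detritus `D`,
plant-available `A`), and the atmospheric N₂O burden `E` attributable to that
hectare's soil emissions. Its assumptions, in brief:

* **Liebig growth.** Per-capita growth is the minimum of an N-limited rate
  (nitrogen-use efficiency ω times N acquisition) and a density-dependent
  rate β/(1 + γ·B_total) standing in for all non-nitrogen resources. The
  switch is a kink, not a discontinuity: the right-hand side stays
  continuous.
* **Demand-driven fixation.** Fixation per unit biomass C tracks the fixer's
  unmet demand at the density-limited growth rate, clamped to
  [F_min, F_max]. The clamp encodes the strategy continuum (obligate /
  incomplete regulator / facultative) and forces the pointwise nesting
  F_obligate ≥ F_incomplete ≥ F_facultative at equal conditions.
* **Linear N₂O emission.** Soil N₂O flux is η·A, a fixed fraction-rate of the
  plant-available pool (the convention of national greenhouse-gas
  inventories); all other plant-available losses (leaching, NO, NH₃, N₂) are
  k·A. Emitted N₂O decays at ψ, the inverse atmospheric lifetime (121 yr).
* **Closed ecosystem otherwise.** Nitrogen enters only by deposition I and
  fixation F·B_F; summing the pool equations in N units yields the exact
  balance d/dt[D + A + B_F/ω_F + B_0/ω_0] = I + F·B_F − (k+η)A − φD, which
  the integrator must conserve (see *Numerical choices*).

Two accounting methods turn a 100-year trajectory into a climate currency
(negative = cooling). Method 1 converts the 100-yr change in biomass C and
in E to annualized CO₂(-equivalents), using the 100-yr global warming
potential of N₂O, 298 kg CO₂ per kg N₂O. Method 2 integrates the radiative
forcing of the continuous sequestration flux (via the four-term CO₂
impulse-response fit: a₀ = 0.2173, a₁ = 0.2240, a₂ = 0.2824, a₃ = 0.2763;
τ = 394.4, 36.54, 4.304 yr) and of the continuous emission flux η·A (decaying
at ψ), with radiative efficiencies converted from W m⁻² ppbv⁻¹ to W m⁻² kg⁻¹
by RE·(M_air/M_gas)·10⁹/T_M. One deliberate dimensional choice: the method-2
N₂O integrand converts the nitrogen-mass flux η·A to N₂O mass (×44/28)
before applying the per-kg-N₂O radiative efficiency, mirroring the method-1
convention. Method 2 inherits a known imperfection of the impulse-response
formulation — the terrestrial sink is already part of the CO₂ removal
processes, so sequestration is partially double-counted; it is used for
trend confirmation, not headline numbers.

## Parameters

Per biome (defaults in `src/nfixclim/data/default_config.yaml`, all
config-overridable):

| symbol | meaning | units | tropical default |
|---|---|---|---|
| ω_F, ω_0 | N-use efficiency (C:N) | kg C (kg N)⁻¹ | 325, 350 |
| ν_F, ν_0 | N uptake coefficient | ha (kg C yr)⁻¹ | 2×10⁻⁴ |
| β_F, β_0 | max growth rate | yr⁻¹ | 1.3, 1.0 |
| γ_F, γ_0 | density dependence | ha (kg C)⁻¹ | 6×10⁻⁴, 1.5×10⁻⁴ |
| μ_F, μ_0 | turnover | yr⁻¹ | 0.05 |
| m, φ | mineralization, detrital loss | yr⁻¹ | 0.15, 0.01 |
| k, η | non-N₂O and N₂O losses of A | yr⁻¹ | 0.1, 0.05 |
| ψ | atmospheric N₂O removal | yr⁻¹ | 1/121 |
| F_max | max fixation per biomass C | kg N (kg C yr)⁻¹ | 1.5×10⁻³ |

The fixer is parameterized as an **early-successional pioneer**: faster
maximum growth (β_F > β_0) but much stronger self-limitation (γ_F ≫ γ_0), and
a per-biomass fixation capacity comparable to a young stand's full N demand.
This configuration produces the mechanism the analysis turns on: while the
stand is nitrogen-limited, fixed N is absorbed into growth (large CO₂
effect, no emissions); once growth is density-limited, sustained fixation
leaks through the soil to N₂O. It also yields the observed successional
narrative — fixers dominate early, are competitively excluded as the canopy
closes, and are excluded fastest where deposition is high.

Study conditions without published values were fixed once as defaults: deposition scenarios
per biome (tropical 0.5 / 5.0 / 6.5 / 11.0 kg N ha⁻¹ yr⁻¹ for
pre-industrial / 2001 / 2006 / 2030; temperate 0.5 / 6.0 / 7.0 / 10.0;
boreal 0.3 / 1.5 / 2.0 / 3.5), FRA-2015 forest areas (tropical 1.770×10⁹ ha,
temperate 1.004×10⁹ including subtropical, boreal 1.224×10⁹), equal biomass
seeding of 10 kg C ha⁻¹ per species (fixer seed zeroed in non-fixer-only
runs), E(0) = 0, and F_min = 0.5·F_max for the incomplete regulator. The
three initial-soil-N levels span roughly ±50 % around a plausible
early-successional detrital stock (tropical D = 15/20/30, A = 0.75/1/1.5
kg N ha⁻¹): initial detritus controls how quickly the non-fixer baseline
establishes, and the moderate band keeps the relative effects insensitive to
it (maximum spread ≈ 0.95 Mg CO₂-eq ha⁻¹ yr⁻¹ across the grid), consistent
with the insensitivity the validity literature reports.

## Calibration

Because the exact study parameter values are not published in retrievable
form, the nominal sets are treated as starting points and calibrated to
published validity anchors per biome: equilibrium total biomass (124 / 145 /
75 Mg C ha⁻¹), the soil-N₂O-emission ceiling (6.97 / 0.29 / 0.13 kg N₂O-N
ha⁻¹ yr⁻¹) and the N-fixation ceiling (29 / 10 / 6 kg N ha⁻¹ yr⁻¹) for
tropical / temperate / boreal forests. The anchor evaluation protocol:
biomass equilibrium is the steady state of the obligate + non-fixer system
at the recent (2006) deposition rate; the two ceilings are maxima over
100-yr obligate runs at the low / 2001 / 2006 deposition rates with
intermediate initial soil N (2030 deposition is excluded because the
validity targets describe behavior under recent deposition). Calibration
optimizes log-multipliers on a minimal, nearly-diagonal free subset —
γ (both species, sets the biomass equilibrium), η (sets the N₂O ceiling) and
F_max (sets the fixation ceiling) — by bounded least squares on relative
anchor residuals (bounds [0.2, 5]); β is available as an additional free
factor. All nine anchors are met to machine-level residuals, far inside the
5 % acceptance tolerance. The calibrated global estimates under 2030
deposition (non-fixer −3.97 Pg C yr⁻¹; obligate relative +0.42, facultative
+0.08, incomplete regulator +0.25) are reported as computed, not tuned to
any published table.

## Numerical choices

* **Integration.** `scipy.integrate.solve_ivp` (LSODA), rtol 10⁻⁸, atol
  10⁻¹⁰, maximum step 0.1 yr, output grid 0.1 yr over 100 yr. The Liebig and
  clamping kinks are handled by the capped step rather than event detection;
  an independent fixed-step RK4 integrator at h = 0.005 yr agrees with the
  adaptive solution to < 10⁻⁴ relative on every pool.
* **Non-negativity.** Fluxes are evaluated on states floored at zero;
  trajectories are accepted only if no pool undershoots beyond −10⁻⁸ (then
  clipped), otherwise the run aborts. There is no extinction floor: excluded
  populations decay asymptotically.
* **Steady states** are located by a 3000-yr spin-up (step cap relaxed to
  1 yr), pinning pools that collapse below 10⁻⁴ to zero, then polishing with
  a root solve of the right-hand side; the active Liebig branch of each
  species is reported. Residuals must be below 10⁻⁷ × state scale.
* **Mass balance.** The cumulative net N flux is integrated alongside the
  state, so the conservation residual is available at solver accuracy; it
  stays below 10⁻⁶ relative on every grid trajectory.
* **Quadrature.** Method-2 forcings use composite trapezoid on the output
  grid; constant-flux cases match closed-form integrals to < 10⁻⁶ relative
  and halving the grid changes results by < 10⁻⁴.
* **Tie-breaks.** The single-pool sweep realizes F = 0 by copying fixer
  physiology into the non-fixer slots (the obligate strategy type requires
  F > 0); the two code paths agree to solver accuracy.

## Synthetic inputs and what the tests show

The study is simulation-only; no external data are read. The synthetic
module generates the study conditions (parameter ensembles with independent
log-uniform multiplicative perturbations; deposition and ψ excluded),
calibrates to anchors, and evaluates the qualitative claims over ensembles.
Passing tests therefore demonstrate internal correctness (conservation,
closed-form limits, oracle agreement) and the robustness of the *qualitative*
conclusions near the calibrated parameterization — not fidelity to any real
forest's fluxes beyond the anchor quantities themselves.

Cross-method sign agreement is asserted only where both methods' net
relative effects are non-negligible (|GWP net| > 0.25 Mg CO₂-eq ha⁻¹ yr⁻¹
and |RF net| > 5 % of the grid maximum): the two methods weight early versus
late fluxes differently, so cells with effects near zero can differ in sign
without contradicting the expectation that the methods agree in substance.
"Negligible" for the facultative strategy at high deposition means
|net| ≤ 0.2 Mg CO₂-eq ha⁻¹ yr⁻¹.

## Known limitations

* No spatial structure, stochasticity, age structure, or mechanistic
  phosphorus/light competition beyond the density-dependent surrogate.
* The anchor system is underdetermined: many parameter vectors reproduce the
  nine anchors, and the global magnitudes (e.g. the obligate relative effect
  of +0.42 Pg C yr⁻¹) carry that structural uncertainty even though the
  signs and ordering are robust under ±10 % parameter perturbations.
* Method 2 inherits the terrestrial-sink double counting of the
  impulse-response formulation, as noted above.
* The 100-yr window is a fixed accounting horizon; no discounting or
  alternative GWP horizons are offered.
* Global upscaling multiplies three per-hectare trajectories by three area
  totals — a deliberate order-of-magnitude construction, not a gridded
  estimate.
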