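# Default study configuration: per-biome parameter sets, nitrogen-deposition
# scenarios, initial pools, calibration anchors, radiative constants, solver
# settings and global forest areas.  All values are overridable from a user
# config file.
#
# Parameter values are literature-plausible nominal choices for each forest
# biome; the calibration routine rescales (gamma, eta, F_max) so that the
# model reproduces the published validity anchors (equilibrium biomass, soil
# N2O emission range, N fixation range).  Deposition rates (kg N/ha/yr) span
# pre-Anthropocene (low), recent (2001/2006) and projected 2030 (SRES A2)
# levels.  Forest areas are FRA 2015 climate-domain totals (ha), with the
# subtropical domain folded into temperate; these are externally sourced
# defaults, not fitted quantities.

solver:
  rtol: 1.0e-8
  atol: 1.0e-10
  max_step: 0.1
  output_step: 0.1
  horizon: 100.0

radiative_constants:
  gwp_n2o: 298.0
  re_co2_ppbv: 1.37e-5
  re_n2o_ppbv: 3.03e-3
  a_0: 0.2173
  a_1: 0.2240
  a_2: 0.2824
  a_3: 0.2763
  tau_1: 394.4
  tau_2: 36.54
  tau_3: 4.304
  M_A: 28.97
  M_CO2: 44.01
  M_N2O: 44.013
  T_M: 5.135e18

global:
  areas_ha:
    tropical: 1.770e9
    temperate: 1.004e9
    boreal: 1.224e9
  forest_sink_pg_c_per_yr: 2.4

experiment:
  deposition_levels: [low, intermediate_2006, high_2030]
  initial_n_levels: [low, intermediate, high]
  compositions: [non_fixer, obligate, facultative, incomplete_regulator]

calibration:
  free_parameters: [gamma, eta, F_max]
  bounds: [0.2, 5.0]
  relative_tolerance: 0.05

biomes:
  tropical:
    parameters:
      omega_F: 325.0
      omega_0: 350.0
      nu_F: 2.0e-4
      nu_0: 2.0e-4
      beta_F: 1.3
      beta_0: 1.0
      gamma_F: 6.0e-4
      gamma_0: 1.5e-4
      mu_F: 0.05
      mu_0: 0.05
      m: 0.15
      phi: 0.01
      I: 6.5
      k: 0.1
      eta: 0.05
      psi: 8.264e-3
    strategy:
      F_max: 1.5e-3
      F_min_fraction: 0.5
    deposition:
      low: 0.5
      intermediate_2001: 5.0
      intermediate_2006: 6.5
      high_2030: 11.0
    initial_soil_n:
      low: {D: 15.0, A: 0.75}
      intermediate: {D: 20.0, A: 1.0}
      high: {D: 30.0, A: 1.5}
    initial_biomass:
      B_F: 10.0
      B_0: 10.0
    anchors:
      biomass_equilibrium: 124000.0   # kg C/ha
      n2o_max: 6.97                   # kg N2O-N/ha/yr
      fixation_max: 29.0              # kg N/ha/yr

  temperate:
    parameters:
      omega_F: 325.0
      omega_0: 350.0
      nu_F: 1.5e-4
      nu_0: 1.5e-4
      beta_F: 0.8
      beta_0: 0.6
      gamma_F: 5.4e-4
      gamma_0: 9.7e-5
      mu_F: 0.04
      mu_0: 0.04
      m: 0.08
      phi: 0.008
      I: 7.0
      k: 0.08
      eta: 0.004
      psi: 8.264e-3
    strategy:
      F_max: 8.0e-4
      F_min_fraction: 0.5
    deposition:
      low: 0.5
      intermediate_2001: 6.0
      intermediate_2006: 7.0
      high_2030: 10.0
    initial_soil_n:
      low: {D: 30.0, A: 1.5}
      intermediate: {D: 40.0, A: 2.0}
      high: {D: 55.0, A: 2.75}
    initial_biomass:
      B_F: 10.0
      B_0: 10.0
    anchors:
      biomass_equilibrium: 145000.0
      n2o_max: 0.29
      fixation_max: 10.0

  boreal:
    parameters:
      omega_F: 325.0
      omega_0: 350.0
      nu_F: 1.0e-4
      nu_0: 1.0e-4
      beta_F: 0.4
      beta_0: 0.3
      gamma_F: 8.0e-4
      gamma_0: 1.2e-4
      mu_F: 0.03
      mu_0: 0.03
      m: 0.03
      phi: 0.003
      I: 2.0
      k: 0.05
      eta: 0.002
      psi: 8.264e-3
    strategy:
      F_max: 1.0e-3
      F_min_fraction: 0.5
    deposition:
      low: 0.3
      intermediate_2001: 1.5
      intermediate_2006: 2.0
      high_2030: 3.5
    initial_soil_n:
      low: {D: 55.0, A: 1.0}
      intermediate: {D: 80.0, A: 1.5}
      high: {D: 115.0, A: 2.25}
    initial_biomass:
      B_F: 10.0
      B_0: 10.0
    anchors:
      biomass_equilibrium: 75000.0
      n2o_max: 0.13
      fixation_max: 6.0
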