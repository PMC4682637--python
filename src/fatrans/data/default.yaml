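# Default physicochemical parameter set for myocardial fatty-acid transfer.
# Human units: concentrations in mmol/l (== mol/m^3), lengths in nm or um.
# Compartment volume fractions and membrane surface densities are rabbit
# left-ventricular morphometry; binding constants are palmitate-albumin
# (three high-affinity sites, average K) and heart-type FABP.

general:
  C_lipid: 8.0e+5        # lipid/water partition coefficient of palmitate
  D_Fa: 4.8e-10          # m^2/s, free Fa in water
  D_mem: 4.0e-12         # m^2/s, Fa inside the bilayer
  h_mem_nm: 5.0
  n_Alb: 3
  d_Cp_nm: 5.0           # membrane reaction rate length (~albumin radius)
  M_Fa: 256.0
  M_Cp_alb: 67000.0
  M_Cp_fabp: 15000.0

compartments:
  cap:                   # capillary plasma; carrier = albumin (Cp from n_Alb * [Alb])
    volume_fraction: 0.094
    D_Cp: 9.35e-11
    K_CpFa: 9.0e-6
    tau_CpFa: 0.01
  ec:                    # endothelial cytoplasm; carrier = FABP (<= 4% of myo)
    volume_fraction: 0.018
    h_diff_nm: 187.0
    D_Cp: 1.87e-10
    K_CpFa: 9.0e-6
    tau_CpFa: 0.01
    Cp_total: 0.007
  is1:                   # pericapillary interstitium; albumin at 86% of plasma
    volume_fraction: 0.019
    h_diff_nm: 160.0
    D_Cp: 9.35e-11
    K_CpFa: 9.0e-6
    tau_CpFa: 0.01
    Cp_ratio_to_cap: 0.86
  myo:                   # cardiomyocyte cytoplasm; carrier = heart FABP
    volume_fraction: 0.731
    D_Cp: 1.87e-10
    K_CpFa: 9.0e-6
    tau_CpFa: 0.01
    Cp_total: 0.170

membranes:
  cap_ec:
    S_per_Vall: 75200.0
  ec_is1:
    S_per_Vall: 82200.0
  is1_myo:
    S_per_Vall: 89100.0

aux_volumes:             # bookkeeping only; is2 storage folds into myo
  is2: 0.060
  ttub: 0.010
  lv: 0.059
  isc: 0.010
  is2_mid_S_per_Vall: 94000.0
  is2_Cp_ratio_to_cap: 0.86

bed:
  z0_um: 800.0
  sigma_cap: 0.5
  d_cap_um: 5.2

experiment:              # experiment A: intermediate albumin
  inlet_Alb: 0.11
  inlet_Fa_total: 0.10
  q_tot: 0.035
  target_extraction: 0.12

numerics:
  n_z: 120
  area_cutoff: 1.0e-4
  dt: 0.02
  t_max: 150.0
  steady_tol: 1.0e-8
  max_outer: 200
  damping: 0.5
  deconv_dt: 0.1
  deconv_smoothing: 1.0e-4
  deconv_max_time: 60.0
  seed: 0
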