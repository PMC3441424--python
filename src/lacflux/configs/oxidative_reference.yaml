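# Calibrated reference parameter set of a typical oxidative brain cell.
# Produced by analysis/01_calibrate_reference.py: with the basal oxidative
# flux fixed at J_PDH = 0.01 mM/s and the basal supply ratio at
# r = J_MCT/J_glyco = 0.43/0.57, the free constants below were fitted to the
# physiological constraint windows and the published steady-state flux
# responses of the stimulation scenarios. Units: mM and s throughout;
# v_max_glyco is in pyruvate-equivalents (2 pyruvate per glucose absorbed
# into the maximal rate).
parameters:
  v_max_MCT: 0.19613919304686137
  K_MCT_L: 1.0732208796721923
  K_MCT_H: 0.00011314661324211104
  v_max_glyco: 0.009820061685131077
  K_glc: 0.05
  K_NAD_g: 0.2999998082748886
  v_max_PDH: 0.015821388597471134
  K_PDH: 0.011593795036936708
  k_shuttle: 0.3142669134432386
  k_f_LDH: 100.0
  k_r_LDH: 0.3490198997016896
  LDH_total: 3.2
  N_tot: 0.5
environment:
  L_e: 1.0                      # resting extracellular lactate, mM
  Glc: 1.0                      # glucose, mM (glycolysis glucose-saturated)
  H_i: 7.065260259963638e-05    # pH_i 7.15, mM
  H_e: 3.9810717055349695e-05   # pH_e 7.40, mM
options:
  mct_form: proton_coupled
  frozen_glycolysis: false
constraints:
  L_i_range: [0.3, 1.5]         # intracellular lactate, mM
  lp_ratio_range: [8.0, 25.0]   # lactate/pyruvate ratio
  redox_range: [0.005, 0.07]    # cytosolic NADH/NAD+
scenarios: {}
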