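# Default soil C/N turnover and inorganic N transformation parameters.
# Pool rate coefficients, efficiencies and routing follow the DAISY
# default parameterisation; inorganic kinetics use the model defaults
# (maximum nitrification rate 5 ug cm-3 d-1 with half-saturation
# 50 ug cm-3, denitrification cap 0.1 d-1, potential denitrification
# 0.1 g gas-N per g CO2-C).
turnover:
  k_som1: 2.7e-6        # d-1, slow native SOM
  k_som2: 1.4e-4        # d-1, fast native SOM
  death_smb1: 1.85e-4   # d-1
  maint_smb1: 1.8e-3    # d-1
  death_smb2: 1.0e-2    # d-1
  maint_smb2: 1.0e-2    # d-1
  k_aom1: 5.0e-3        # d-1, slow added organic matter
  k_aom2: 5.0e-2        # d-1, fast added organic matter
  efficiency: 0.60      # substrate utilisation efficiency
  cn_smb: 6.7
  cn_som: 11.0
  temperature_optimum: 20.0   # deg C
  clay_protection_slope: 2.0
  clay_protection_floor: 0.2
inorganic:
  vn_star: 5.0          # ug cm-3 d-1
  kn: 50.0              # ug cm-3
  kd: 0.1               # d-1
  alpha_d: 0.1          # g gas-N per g CO2-C
  k_urea: 0.4           # d-1
  k_vol: 2.0            # d-1
  vol_depth: 10.0       # cm
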