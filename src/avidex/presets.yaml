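# Pre-calibrated surface profiles (calibrate_profile, n=4000 curves, seed=7)
G7-pPDL1:
  bond_count_pmf:
    0: 0.0
    1: 0.11000000000000001
    2: 0.534
    3: 0.2225
    4: 0.1335
  force_floor: 450.0
  loading_stiffness: 21983.944199929785
  min_bond_gap: 3.0
  multibond_logmean: 6.3112880542784415
  multibond_logsd: 0.8
  name: G7-pPDL1
  noise_sd: 30.0
  nonspecific_depth: 50.0
  nonspecific_logsd: 0.4
  rupture_force_logmean: 5.846784471053372
  rupture_force_logsd: 0.55
  rupture_sep_range:
  - 5.0
  - 60.0
  sample_spacing: 0.5
  z_max: 160.0
G7-pPDL1-scr:
  bond_count_pmf:
    0: 0.7000000000000001
    1: 0.225
    2: 0.04499999999999999
    3: 0.022499999999999996
    4: 0.007499999999999998
  force_floor: 450.0
  loading_stiffness: 40000.0
  min_bond_gap: 3.0
  multibond_logmean: 6.351807204557667
  multibond_logsd: 0.7
  name: G7-pPDL1-scr
  noise_sd: 30.0
  nonspecific_depth: 50.0
  nonspecific_logsd: 0.4
  rupture_force_logmean: 6.218275811933144
  rupture_force_logsd: 0.6
  rupture_sep_range:
  - 5.0
  - 60.0
  sample_spacing: 0.5
  z_max: 160.0
aPD-L1:
  bond_count_pmf:
    0: 0.09000000000000002
    1: 0.2
    2: 0.42599999999999993
    3: 0.17750000000000002
    4: 0.10649999999999998
  force_floor: 450.0
  loading_stiffness: 10758.772191061227
  min_bond_gap: 3.0
  multibond_logmean: 5.848845654842142
  multibond_logsd: 0.6
  name: aPD-L1
  noise_sd: 30.0
  nonspecific_depth: 50.0
  nonspecific_logsd: 0.4
  rupture_force_logmean: 5.848845654842142
  rupture_force_logsd: 0.6
  rupture_sep_range:
  - 5.0
  - 60.0
  sample_spacing: 0.5
  z_max: 160.0
pPDL1:
  bond_count_pmf:
    0: 0.3
    1: 0.34
    2: 0.216
    3: 0.09
    4: 0.054
  force_floor: 450.0
  loading_stiffness: 8994.131076653402
  min_bond_gap: 3.0
  multibond_logmean: 5.8427040038271265
  multibond_logsd: 0.6
  name: pPDL1
  noise_sd: 30.0
  nonspecific_depth: 50.0
  nonspecific_logsd: 0.4
  rupture_force_logmean: 5.8427040038271265
  rupture_force_logsd: 0.6
  rupture_sep_range:
  - 5.0
  - 60.0
  sample_spacing: 0.5
  z_max: 160.0
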