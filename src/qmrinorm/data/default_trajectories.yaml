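# Default generative trajectory parameters for the synthetic cohort.
#
# Units: R1 and R2* in 1/s, chi in ppm; ages in years.  R1 follows a
# quadratic (inverted-U) trajectory peaking between 45 and 60 years;
# R2* and chi increase linearly with age.  Network A = striatum
# (caudate, putamen); network B = pallidum / nigra / red nucleus /
# subthalamic / ventral pallidum.  Loadings are scaled so that
# within-network residual correlations fall in the 0.6-0.85 range
# reported for deviation scores in these nuclei.  Values are
# illustrative of the literature, not fitted to any dataset.
trajectories:
  # --- R1 (quadratic, peak 45-60 y; ~0.1 1/s amplitude over adulthood) ---
  - {roi: Cau,  metric: R1, intercept: 0.4796, beta_age: 0.0104, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: A, network_loading: 0.04}
  - {roi: Pu,   metric: R1, intercept: 0.6000, beta_age: 0.0100, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: A, network_loading: 0.04}
  - {roi: GPe,  metric: R1, intercept: 0.7475, beta_age: 0.0110, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: B, network_loading: 0.04}
  - {roi: GPi,  metric: R1, intercept: 0.7751, beta_age: 0.0114, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: B, network_loading: 0.04}
  - {roi: NAcc, metric: R1, intercept: 0.2775, beta_age: 0.0130, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: none}
  - {roi: SNc,  metric: R1, intercept: 0.6975, beta_age: 0.0110, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: B, network_loading: 0.04}
  - {roi: SNr,  metric: R1, intercept: 0.7364, beta_age: 0.0112, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: B, network_loading: 0.04}
  - {roi: RN,   metric: R1, intercept: 0.7084, beta_age: 0.0108, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: B, network_loading: 0.04}
  - {roi: STN,  metric: R1, intercept: 0.6975, beta_age: 0.0110, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: B, network_loading: 0.04}
  - {roi: VP,   metric: R1, intercept: 0.5656, beta_age: 0.0124, beta_age2: -1.0e-4, beta_sex: 0.005, beta_hemi: 0.010, noise_sd0: 0.030, noise_sd_slope: 0.0002, network_id: B, network_loading: 0.04}
  # --- R2* (linear increase) ---
  - {roi: Cau,  metric: R2star, intercept: 16.10, beta_age: 0.05, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: A, network_loading: 5.0}
  - {roi: Pu,   metric: R2star, intercept: 17.30, beta_age: 0.15, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: A, network_loading: 5.0}
  - {roi: GPe,  metric: R2star, intercept: 28.92, beta_age: 0.06, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: B, network_loading: 5.0}
  - {roi: GPi,  metric: R2star, intercept: 31.10, beta_age: 0.05, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: B, network_loading: 5.0}
  - {roi: NAcc, metric: R2star, intercept: 15.46, beta_age: 0.03, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: none}
  - {roi: SNc,  metric: R2star, intercept: 26.38, beta_age: 0.09, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: B, network_loading: 5.0}
  - {roi: SNr,  metric: R2star, intercept: 28.56, beta_age: 0.08, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: B, network_loading: 5.0}
  - {roi: RN,   metric: R2star, intercept: 24.20, beta_age: 0.10, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: B, network_loading: 5.0}
  - {roi: STN,  metric: R2star, intercept: 26.56, beta_age: 0.08, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: B, network_loading: 5.0}
  - {roi: VP,   metric: R2star, intercept: 23.10, beta_age: 0.05, beta_sex: 0.3, beta_hemi: 0.5, noise_sd0: 2.0, noise_sd_slope: 0.02, network_id: B, network_loading: 5.0}
  # --- chi (linear increase, ppm) ---
  - {roi: Cau,  metric: chi, intercept: 0.0292,  beta_age: 0.0006, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: A, network_loading: 0.03}
  - {roi: Pu,   metric: chi, intercept: -0.0016, beta_age: 0.0012, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: A, network_loading: 0.03}
  - {roi: GPe,  metric: chi, intercept: 0.1128,  beta_age: 0.0004, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: B, network_loading: 0.03}
  - {roi: GPi,  metric: chi, intercept: 0.1228,  beta_age: 0.0004, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: B, network_loading: 0.03}
  - {roi: NAcc, metric: chi, intercept: 0.0146,  beta_age: 0.0003, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: none}
  - {roi: SNc,  metric: chi, intercept: 0.0856,  beta_age: 0.0008, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: B, network_loading: 0.03}
  - {roi: SNr,  metric: chi, intercept: 0.1056,  beta_age: 0.0008, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: B, network_loading: 0.03}
  - {roi: RN,   metric: chi, intercept: 0.0656,  beta_age: 0.0008, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: B, network_loading: 0.03}
  - {roi: STN,  metric: chi, intercept: 0.0892,  beta_age: 0.0006, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: B, network_loading: 0.03}
  - {roi: VP,   metric: chi, intercept: 0.0528,  beta_age: 0.0004, beta_sex: 0.002, beta_hemi: 0.004, noise_sd0: 0.015, noise_sd_slope: 0.0001, network_id: B, network_loading: 0.03}
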