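# Full default configuration: the acquisition protocol, cohort design,
# fit settings and analysis settings of the emulated study.
seed: 0
protocol:
  spgr_flip_deg:
  - 3.0
  - 17.0
  spgr_tr_s: 0.01
  bssfp_flip_deg:
  - 15.0
  - 35.0
  bssfp_tr_s: 0.00393
  mt_trf_ms:
  - 0.12
  - 0.227
  - 0.424
  - 0.8
  - 1.5
  mt_trf_flip_deg: 35.0
  mt_alpha_flip_deg:
  - 5.0
  - 12.5
  - 20.0
  - 27.5
  - 35.0
  mt_alpha_trf_ms: 0.12
  mt_tr_endpoints_ms:
  - 2.55
  - 3.93
  b1map_flip_deg: 30.0
  dwi_bval: 900.0
  dwi_n_b0: 10
phantom:
  grid_shape:
  - 48
  - 48
  - 48
  voxel_mm: 1.3
  dwi_grid_shape:
  - 31
  - 31
  - 31
  dwi_voxel_mm: 2.0
  snr: 80.0
  dwi_snr: 60.0
  rician: false
  b1_amplitude: 0.1
  b1_map_noise_sd: 0.005
  n_subjects: 19
  schedule_months:
  - 0
  - 2
  - 4
  - 6
  - 8
  - 10
  - 12
  - 24
  lesions_by_subject:
    S01:
    - 2
    - 4
    - 4
    - 6
    - 6
    - 8
    - 8
    - 10
    - 10
    S02:
    - 10
    - 10
    - 10
    - 10
    S03:
    - 4
    - 6
    - 8
    S04:
    - 2
    - 4
    S05:
    - 4
    S06:
    - 6
    S07:
    - 6
  missed_exams:
  - - S03
    - 2
  - - S04
    - 10
  - - S04
    - 12
  - - S05
    - 8
  - - S06
    - 8
  - - S06
    - 12
  missed_dti:
  - - S01
    - 0
  - - S02
    - 0
  - - S03
    - 12
  - - S04
    - 6
  - - S05
    - 2
  - - S07
    - 24
  lesion_volume_mean_mm3: 71.0
  lesion_volume_sd_mm3: 60.0
  lesion_volume_range_mm3:
  - 12.0
  - 201.0
  lesion_axis_ratio_range:
  - 1.0
  - 2.5
  mask_shrink: 0.8
  min_mask_voxels: 3
  severity_clip: 2.0
  tissues:
    NAWM:
      F: 0.157
      kf: 4.45
      T1: 0.779
      T2: 0.045
      M0: 1.0
      eigenvalues:
      - 0.0013
      - 0.00045
      - 0.00045
    GM:
      F: 0.1
      kf: 2.4
      T1: 1.1
      T2: 0.08
      M0: 1.0
      eigenvalues:
      - 0.00095
      - 0.00075
      - 0.00075
    CSF:
      F: 0.0
      kf: 0.0
      T1: 4.0
      T2: 2.0
      M0: 1.0
      eigenvalues:
      - 0.003
      - 0.003
      - 0.003
  mti_anchors:
    F:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - -1.2
      - 2.55
      - 4
    - - -4.0
      - -12.3
      - 7.7
      - 14
    - - -2.0
      - -14.7
      - 4.8
      - 19
    - - 0.0
      - -70.2
      - 4.7
      - 21
    - - 2.0
      - -55.9
      - 8.15
      - 71
    - - 8.0
      - -55.9
      - 8.15
      - 71
    - - 24.0
      - -55.9
      - 8.15
      - 71
    kf:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - -3.7
      - 12.8
      - 4
    - - -4.0
      - -12.7
      - 5.5
      - 14
    - - -2.0
      - -15.3
      - 5.3
      - 19
    - - 0.0
      - -73.1
      - 4.25
      - 21
    - - 2.0
      - -59.1
      - 5.75
      - 71
    - - 8.0
      - -59.1
      - 5.75
      - 71
    - - 24.0
      - -59.1
      - 5.75
      - 71
    T1:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - 1.9
      - 7.95
      - 4
    - - -4.0
      - 6.7
      - 5.0
      - 14
    - - -2.0
      - 10.3
      - 4.1
      - 19
    - - 0.0
      - 74.5
      - 20.8
      - 21
    - - 2.0
      - 42.9
      - 12.8
      - 71
    - - 8.0
      - 42.9
      - 12.8
      - 71
    - - 24.0
      - 42.9
      - 12.8
      - 71
    T2:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - -1.1
      - 5.15
      - 4
    - - -4.0
      - 6.6
      - 5.3
      - 14
    - - -2.0
      - 9.9
      - 4.0
      - 19
    - - 0.0
      - 122.5
      - 47.6
      - 21
    - - 2.0
      - 60.0
      - 18.35
      - 71
    - - 8.0
      - 60.0
      - 18.35
      - 71
    - - 24.0
      - 60.0
      - 18.35
      - 71
    MTR:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - 0.1
      - 2.85
      - 4
    - - -4.0
      - -2.3
      - 1.1
      - 14
    - - -2.0
      - -3.0
      - 1.15
      - 19
    - - 0.0
      - -27.7
      - 3.7
      - 21
    - - 2.0
      - -19.1
      - 3.75
      - 71
    - - 8.0
      - -19.1
      - 3.75
      - 71
    - - 24.0
      - -19.1
      - 3.75
      - 71
  dti_anchors:
    FA:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - -9.3
      - 13.45
      - 39
    - - -2.0
      - -9.3
      - 13.45
      - 39
    - - 0.0
      - -38.5
      - 6.75
      - 21
    - - 2.0
      - -27.7
      - 7.05
      - 60
    - - 8.0
      - -27.7
      - 7.05
      - 60
    - - 24.0
      - -27.7
      - 7.05
      - 60
    MD:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - 6.8
      - 6.85
      - 39
    - - -2.0
      - 6.8
      - 6.85
      - 39
    - - 0.0
      - 37.5
      - 8.65
      - 21
    - - 2.0
      - 29.6
      - 5.65
      - 60
    - - 8.0
      - 29.6
      - 5.65
      - 60
    - - 24.0
      - 29.6
      - 5.65
      - 60
    AD:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - 3.6
      - 5.05
      - 39
    - - -2.0
      - 3.6
      - 5.05
      - 39
    - - 0.0
      - 18.4
      - 7.7
      - 21
    - - 2.0
      - 17.8
      - 7.15
      - 60
    - - 8.0
      - 17.8
      - 7.15
      - 60
    - - 24.0
      - 17.8
      - 7.15
      - 60
    RD:
    - - -12.0
      - 0.0
      - 0.0
      - 21
    - - -10.0
      - 10.6
      - 8.9
      - 39
    - - -2.0
      - 10.6
      - 8.9
      - 39
    - - 0.0
      - 60.6
      - 12.95
      - 21
    - - 2.0
      - 45.6
      - 6.55
      - 60
    - - 8.0
      - 45.6
      - 6.55
      - 60
    - - 24.0
      - 45.6
      - 6.55
      - 60
fit:
  T1r: 1.0
  G0: 1.4e-05
  rf_shape_factor: 1.0
  qmt_bounds_F:
  - 0.0
  - 0.5
  qmt_bounds_kf:
  - 0.0
  - 50.0
  qmt_init:
  - 0.1
  - 3.0
  n_workers: 1
analysis:
  confidence: 0.95
  alpha: 0.05
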