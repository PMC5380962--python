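# Demo scenario: expanding bloom patch with k_e = 1,100 m^2/s ground truth,
# tracked at the 0.13 mg m^-3 chlorophyll contour over a 40 m mixed layer.
seed: 7
field:
  lon_range: [192.0, 216.0]
  lat_range: [25.0, 39.0]
  grid_step: 0.125      # degrees
  time_span: 60.0       # days
  time_step: 1.0
eddies:
  eddy_length_scale_km: 150.0
  rms_speed: 0.08       # m/s
  n_modes: 24
  evolution_timescale_days: 20.0
bloom:
  center: [202.0, 32.0]
  A0_km2: 10000.0
  k_e_m2_s: 1100.0
  peak: 0.16            # mg/m^3
  background: 0.1
  cloud_fraction: 0.0
tracking:
  level: 0.13
mld:
  value: 40.0           # m
npz:
  mu: 1.6               # /d
  k_N: 0.5              # mmol N/m^3
  G: 0.12               # /d
  k_P: 0.5
  N0: 1.0
  t_end: 600.0
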