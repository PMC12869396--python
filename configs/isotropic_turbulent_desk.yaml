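params:
  lambda_scale: 96.86
  delta_exp: 1.54
  beta_width: 0.08
  c0: 1.0
  isotropic: true
corr_length: 5.0
corr_time: 5.0
n_sensors: 500
radius: 25.0
mechanism: proprioceptive
eta: 0.0
corrected: false
n_realizations: 50
master_seed: 2
min_detections: 2
domain_lambdas: 30.0
field_dx: 20.0
field_dy: 12.0
y_half: 144.0
test_nx: 9
test_ny: 1
test_x_frac:
- 0.1
- 0.95
test_y_half: 30.0
p_floor: 1.0e-06
raw_scale: 1.0
patch_spacing: null
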