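# Example pipeline configuration (desk-scale demo).
# Omitted keys fall back to the protocol defaults: Morlet width 5,
# bands theta 4-7 / alpha 8-12 / beta 13-30 Hz, TOIs post-S1 [-2500,-1500),
# pre-S2 [-1000,0), post-S2 [0,1000) ms, top fraction 0.01, DBSCAN minPts 2
# and eps factor 1.5, lambda 0.05, 256 Hz, epochs [-7000, 2000) ms.
seed: 1

behavior:
  n_hc: 62
  n_gts: 54
  binding_cost_ms: 35.0
  error_binding_cost: 0.09

eeg:
  n_hc: 8
  n_gts: 8
  n_channels: 32
  grid_radius_m: 0.06
  grid_spacing_m: 0.015
  trials_per_condition: 12
  coupling_rho: 0.6
  epoch_window_ms: [-3000.0, 1500.0]
  sources:
    - position: [0.02, 0.02, 0.03]
      band: theta
      amplitudes:
        post_s1: {all: 30.0}
        pre_s2: {all: 30.0}
        post_s2: {RAFR: 45.0, all: 30.0}

tfr:
  decim: 4
  bands:
    theta: [4.0, 7.0]

cluster:
  fraction: 0.05
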