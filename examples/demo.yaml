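# Demo pipeline configuration: small control-condition ensemble.
seed: 7
generator:
  preset: control        # control | mild | moderate | strong
  n_condensates: 400
  duration: 120.0        # s, per-track observation horizon
  frame_interval: 0.5    # s
  intrinsic_noise_sd: 0.1
  obs_noise_sd: 0.05
  detection_threshold: 1.0
model:
  v_A: 1.54e-7           # um^3 / IU
  v_W: 2.34e-7
fitting:
  window: [0.65, 0.93]   # stoichiometry validity window of the volume relation
  n_bins: 24
  min_count: 20
  n_boot: 50
  min_amount: 0.5
io:
  tracks: null           # path to an existing track TSV; null -> simulate
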