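# Demo pipeline: simulate a two-bound-state nuclear factor, then run the
# survival (residence-time) and MSD analyses on the simulated tracks.
#   smt pipeline --config examples/demo.yaml --seed 9 --out demo_out
seed: 9
out_dir: demo_out
stages: [simulate, survival, msd, states]
meta:
  pixel_size: 0.11      # µm/px
  exposure: 0.2         # s
  dark_interval: 0.0    # s; >0 for time-lapse imaging with dark periods
simulate:
  n_molecules: 500
  n_frames: 150
  nucleus_radius: 1.0          # µm, diploid yeast nucleus
  localization_sigma: 0.03     # µm (~30 nm precision)
  bleach_prob_per_exposure: 0.02
  depth_of_field: 0.4          # µm (HILO)
  states:
    - {label: bound_nonspecific, D: 0.0}
    - {label: bound_specific, D: 0.0}
    - {label: diffusing, D: 1.0}
  # row -> column transition rates (1/s): NS unbinds at 1/2 s^-1,
  # specific at 1/10 s^-1; diffusing molecules defocalize before rebinding
  switch_rates:
    - [0, 0, 0.5]
    - [0, 0, 0.1]
    - [0, 0, 0]
  initial_state_probs: [0.6, 0.4, 0.0]
survival:
  r_max: 0.22   # µm, bound-call radius (~2 px)
  n_min: 3      # frames
  correction: intrinsic
msd:
  max_lag: 10
states:
  k_max: 3
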