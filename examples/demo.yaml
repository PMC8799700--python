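# Desk-scale end-to-end demo: simulate a 6-dyad cohort, classify pain states,
# estimate directed facial causality on the pain-expression sub-grid, run
# pseudo-dyad inference, and regress brain concordance on the facial score.
out_dir: demo_out
seed: 1
n_dyads: 6
dyad:
  rest_s: 2.0
  stim_s: 3.0
  rating_s: 2.0
  n_blocks: 8
  block_duration_range_s: [3.0, 4.5]
pain:
  n_trials_per_condition: 2
  rest_s: 2.0
  cue_s: 4.0
  stim_s: 5.0
  rating_s: 2.0
reservoir:
  n_units: 25
  n_reservoirs: 1
  washout_frames: 5
channels: [AU28_lip_suck, AU43_eye_closure, AU07_lid_tighten, AU04_brow_furrow]
inference:
  alpha: 0.05
  cap: 12
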