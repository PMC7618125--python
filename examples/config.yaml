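# Desk-scale synthetic analysis: full pipeline in a couple of minutes.
# Scale n_subjects / mask boxes / n_perm up for a production-sized run
# (the study-sized defaults are StudyDesign's: 3 voices x 8 clips x 3 reps,
# 24 null trials, 4 runs; 26 subjects; n_perm 10000).
seed: 1

design:
  n_clips_per_identity: 8

mask:
  shape: [36, 10, 5]
  signal_box: [[0, 10], [0, 10], [0, 5]]
  null_box: [[26, 36], [0, 10], [0, 5]]

geometry:
  within: {Familiar: 0.8, Lab: 0.4, New: 0.4}
  between: 1.0
  noise_sd: 0.5

simulation:
  n_subjects: 12

searchlight:
  k: 100

group:
  n_perm: 500
  threshold: 1.96

behavior:
  n_trials_per_category: 96
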