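# Desk-scale demo: 60 subjects, 16^3 volumes, one mean-shift ROI and a
# global texture-complexity effect.
seed: 1
out: run
cohort:
  n_subjects: 60
  volume_shape: [16, 16, 16]
  group_fraction: 0.5
  noise_sd: 0.02
  subject_sd: 0.03
  n_gray_rois: 4
  n_white_rois: 2
  effects:
    - kind: mean_shift
      target_roi_ids: [1]
      magnitude: 1.2
      direction: 1
    - kind: texture_complexity
      magnitude: 1.5
      direction: 1
prep:
  target_shape: [16, 16, 16]
model:
  epochs: 12
  batch_size: 8
  learning_rate: 0.001
features:
  alpha: 0.05
roi:
  epochs: 8
  top_k: 3
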