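# Minutes-scale end-to-end demo: synthetic cohort -> augmentation -> MFCC
# fusion -> 2-session ensemble -> ablation + activation maps.
# Equivalent to lungsound.config.demo_config(seed=0).
seed: 0
synth:
  n_subjects: 60
  class_proportions: [0.334, 0.333, 0.333]
  duration_s: 6.0
  snr_db: 30.0
augment_policy:
  multiplicity:
    wheeze: 1
    fine_crackle: 2
model:
  variant: cnn_lstm_mfcc
  stage_widths: [8, 16, 32, 64]
train:
  epochs: 12
  batch_size: 8
  n_sessions: 2
  lr_start: 0.003
  lr_end: 0.0015
ablation_subsets:
  - [BRUL]
  - [BRUL, BLUL, BLLL, BRLL]
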