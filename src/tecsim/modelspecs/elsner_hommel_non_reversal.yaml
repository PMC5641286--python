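name: elsner_hommel
layers:
- name: vis_shape
  level: sensory
  codes:
  - vis_square
- name: aud_pitch
  level: sensory
  codes:
  - aud_high
  - aud_low
- name: hap_loc
  level: sensory
  codes:
  - key_left
  - key_right
- name: shape
  level: feature
  codes:
  - Square
- name: pitch
  level: feature
  codes:
  - High
  - Low
- name: location
  level: feature
  codes:
  - Left
  - Right
- name: kind
  level: feature
  codes:
  - Sound
  - Key
- name: task
  level: task
  codes:
  - T1
  - T2
- name: motor
  level: motor
  codes:
  - M1
  - M2
links:
- sensory: vis_square
  feature: Square
- sensory: aud_high
  feature: High
- sensory: aud_low
  feature: Low
- sensory: key_left
  feature: Left
- sensory: key_right
  feature: Right
- sensory: aud_high
  feature: Sound
- sensory: aud_low
  feature: Sound
- sensory: key_left
  feature: Key
- sensory: key_right
  feature: Key
effects:
  M1:
  - key_left
  - aud_low
  M2:
  - key_right
  - aud_high
defaults:
  sensory_feature: 0.5063
  feature_sensory: 0.9098
  feature_task: 0.7195
  task_feature: 0.9437
  response_task: 0.2633
network:
  d_a: 0.082
  gamma: 0.3
  na: 6.0472
  qa: 0.5936
  VT: 0.3847
  noise_mean: 0.0
  noise_sd: 0.01
  ext_input: 0.991
  response_threshold: 0.7109
  resting_level: 0.0
  max_cycles: 250
  w_exc_inh: 0.7523
  w_inh: -0.6981
learning:
  d_w: 0.0819
  LT: 0.4818
  n_learning_trials: 20
  effect_cycles: 50
  clamp_motor: true
task:
  rules:
  - stimulus:
    - Square
    task: T1
    response:
    - Key
  - stimulus:
    - Square
    task: T2
    response:
    - Key
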