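name: inversion_key
layers:
- name: aud_pitch
  level: sensory
  codes:
  - aud_high
  - aud_low
- name: aud_loc
  level: sensory
  codes:
  - aud_left
  - aud_right
- name: hap_loc
  level: sensory
  codes:
  - key_left
  - key_right
- name: vis_loc
  level: sensory
  codes:
  - light_left
  - light_right
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
  - Key
  - Light
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
- sensory: aud_high
  feature: High
- sensory: aud_low
  feature: Low
- sensory: aud_left
  feature: Left
- sensory: aud_right
  feature: Right
- sensory: key_left
  feature: Left
- sensory: key_right
  feature: Right
- sensory: light_left
  feature: Left
- sensory: light_right
  feature: Right
- sensory: key_left
  feature: Key
- sensory: key_right
  feature: Key
- sensory: light_left
  feature: Light
- sensory: light_right
  feature: Light
effects:
  M1:
  - key_left
  - light_right
  M2:
  - key_right
  - light_left
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
    - High
    task: T1
    response:
    - Left
    - Key
  - stimulus:
    - Low
    task: T2
    response:
    - Right
    - Key
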