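name: kunde_consistent
layers:
- name: vis_color
  level: sensory
  codes:
  - vis_red
  - vis_green
- name: aud_intensity
  level: sensory
  codes:
  - aud_loud
  - aud_soft
- name: hap_intensity
  level: sensory
  codes:
  - press_hard
  - press_soft
- name: color
  level: feature
  codes:
  - Red
  - Green
- name: intensity
  level: feature
  codes:
  - Forceful
  - Gentle
- name: kind
  level: feature
  codes:
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
- sensory: vis_red
  feature: Red
  w_up: 0.6
- sensory: vis_green
  feature: Green
  w_up: 0.6
- sensory: aud_loud
  feature: Forceful
- sensory: aud_soft
  feature: Gentle
- sensory: press_hard
  feature: Forceful
- sensory: press_soft
  feature: Gentle
- sensory: press_hard
  feature: Key
- sensory: press_soft
  feature: Key
effects:
  M1:
  - press_hard
  - aud_loud
  M2:
  - press_soft
  - aud_soft
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
    - Red
    task: T1
    response:
    - Forceful
    - Key
  - stimulus:
    - Green
    task: T2
    response:
    - Gentle
    - Key
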