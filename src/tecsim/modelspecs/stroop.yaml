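name: stroop
layers:
- name: vis_ink
  level: sensory
  codes:
  - ink_red
  - ink_green
- name: vis_word
  level: sensory
  codes:
  - word_red
  - word_green
- name: aud_speech
  level: sensory
  codes:
  - say_red
  - say_green
- name: ink
  level: feature
  codes:
  - RedInk
  - GreenInk
- name: word
  level: feature
  codes:
  - WordRed
  - WordGreen
- name: kind
  level: feature
  codes:
  - Speech
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
- sensory: ink_red
  feature: RedInk
- sensory: ink_green
  feature: GreenInk
- sensory: word_red
  feature: WordRed
- sensory: word_green
  feature: WordGreen
- sensory: say_red
  feature: WordRed
- sensory: say_green
  feature: WordGreen
- sensory: say_red
  feature: Speech
- sensory: say_green
  feature: Speech
effects:
  M1:
  - say_red
  M2:
  - say_green
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
    - RedInk
    task: T1
    response:
    - WordRed
    - Speech
  - stimulus:
    - GreenInk
    task: T2
    response:
    - WordGreen
    - Speech
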