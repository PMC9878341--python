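name: diet_intercausal
target: T2D
target_state: "Yes"
branch_variable: DIET
steps:
  - [AGE, 48-62]
  - [GENDER, Men]
  - [SMOKING, Former smoker]
  - [PA, "No"]
  - [BMI, Obesity]
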