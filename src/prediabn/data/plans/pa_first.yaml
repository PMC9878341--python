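name: pa_first
target: T2D
target_state: "Yes"
branch_variable: PA
steps:
  - [AGE, 48-62]
  - [FLI, More 60]
  - [HbA1c, More 6.0]
  - [BMI, Obesity]
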