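name: fli_first
target: T2D
target_state: "Yes"
branch_variable: FLI
steps:
  - [HbA1c, More 6.0]
  - [AGE, 48-62]
  - [PA, "No"]
  - [BMI, Obesity]
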