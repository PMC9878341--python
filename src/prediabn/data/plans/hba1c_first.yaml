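name: hba1c_first
target: T2D
target_state: "Yes"
branch_variable: HbA1c
steps:
  - [AGE, 48-62]
  - [PA, "No"]
  - [FLI, More 60]
  - [BMI, Obesity]
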