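name: age_first
target: T2D
target_state: "Yes"
branch_variable: AGE
steps:
  - [PA, "No"]
  - [BMI, Obesity]
  - [FLI, More 60]
  - [HbA1c, More 6.0]
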