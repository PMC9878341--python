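name: bmi_first
target: T2D
target_state: "Yes"
branch_variable: BMI
steps:
  - [HbA1c, More 6.0]
  - [FLI, More 60]
  - [PA, "No"]
  - [AGE, 48-62]
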