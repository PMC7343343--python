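# Base-case cohort: age 57, 20-year horizon, synthetic life table calibrated
# to the Swedish general-population comparator, reference JAK2 trajectory.
start_age: 57
horizon_years: 20
life_table: synthetic
trajectory: default
risk_set: base_case
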