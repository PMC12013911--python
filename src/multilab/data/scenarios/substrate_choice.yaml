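# Color-morph contrast in repeated green/brown substrate choices
archetype: binary_repeated_choice
n_labs: 3
units_per_group_per_lab: 31
alpha: 0.0
beta: 0.15
lab_intercept_sd: 0.3
lab_slope_sd: 0.0
unit_re_sd: 1.0
olre_sd: 0.0
residual_sd: 1.0
n_timepoints: 50
availability_prob: 0.151
response_ceiling: null
transform: none
group_size: 3
treatment_levels: [brown, green]
outcome_id: substrate_choice
seed: 0
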