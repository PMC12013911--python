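# Starvation effect on distance moved (sqrt scale), homogeneous labs
archetype: gaussian_two_group
n_labs: 3
units_per_group_per_lab: 30
alpha: 4.5
beta: 3.43
lab_intercept_sd: 0.4
lab_slope_sd: 0.0
unit_re_sd: 0.0
olre_sd: 0.0
residual_sd: 1.9
n_timepoints: 1
availability_prob: 1.0
response_ceiling: 144.0
transform: sqrt
group_size: 3
treatment_levels: [control, starved]
outcome_id: distance_moved
seed: 0
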