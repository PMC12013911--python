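# Life-stage contrast in per-dish flour-choice counts (3 individuals/dish)
archetype: dish_proportion
n_labs: 3
units_per_group_per_lab: 36
alpha: 0.13
beta: -0.41
lab_intercept_sd: 0.3
lab_slope_sd: 0.0
unit_re_sd: 0.5
olre_sd: 0.5
residual_sd: 1.0
n_timepoints: 14
availability_prob: {larvae: 1.0, adult: 0.334}
response_ceiling: null
transform: none
group_size: 3
treatment_levels: [larvae, adult]
outcome_id: niche_choice
seed: 0
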