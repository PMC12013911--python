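# Same design with between-lab effect heterogeneity calibrated so that
# typically about one of three labs misses significance
archetype: gaussian_two_group
n_labs: 3
units_per_group_per_lab: 30
alpha: 3.5
beta: -1.67
lab_intercept_sd: 0.3
lab_slope_sd: 1.2
unit_re_sd: 0.0
olre_sd: 0.0
residual_sd: 0.8
n_timepoints: 1
availability_prob: 1.0
response_ceiling: 600.0
transform: log1p
group_size: 3
treatment_levels: [control, starved]
outcome_id: pci_duration
seed: 0
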