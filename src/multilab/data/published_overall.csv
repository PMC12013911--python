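outcome_id,estimate,se,ci_low,ci_high,p_value,k
pci_duration,-1.67,0.62,-2.88,-0.46,0.01,3
distance_moved,3.43,0.72,2.01,4.84,0.001,3
substrate_choice,0.15,0.26,-0.36,0.66,0.58,3
niche_choice,-0.41,0.21,-0.78,-0.00,0.05,3
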