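lab_id,outcome_id,estimate,se,ci_low,ci_high,p_value,inference
Lab A,pci_duration,-2.70,0.20,-3.1,-2.29,0.001,published
Lab B,pci_duration,-0.81,0.55,-1.89,0.28,0.15,published
Lab C,pci_duration,-1.17,0.47,-2.09,-0.25,0.02,published
Lab A,distance_moved,4.01,0.48,3.07,4.95,0.001,published
Lab B,distance_moved,1.87,0.77,0.36,3.39,0.02,published
Lab C,distance_moved,4.25,0.72,2.83,5.66,0.001,published
Lab A,substrate_choice,0.34,0.24,-0.13,0.82,0.16,published
Lab B,substrate_choice,-0.04,0.20,-0.44,0.36,0.83,published
Lab C,substrate_choice,0.17,0.17,-0.18,0.51,0.34,published
Lab A,niche_choice,-0.48,0.18,-0.84,-0.12,0.01,published
Lab B,niche_choice,-0.16,0.09,-0.33,0.01,0.06,published
Lab C,niche_choice,-0.82,0.16,-1.13,-0.5,0.001,published
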