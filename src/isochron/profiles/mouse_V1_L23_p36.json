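{
 "age_days": 36,
 "axon_branch_rate": 0.18,
 "axon_synapse_rate": 1.0,
 "axons_per_soma_mean": 30.0,
 "bouton_volume_mean": 0.12,
 "excitatory_shaft_fraction": 0.24,
 "filopodia_rate": 0.03,
 "layer": "L23",
 "mito_density_mean": 26000.0,
 "mito_synapse_corr": 0.4,
 "name": "mouse_V1_L23_p36",
 "psd_logmean": 10.3,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.28,
 "soma_synapse_mean": 66.0,
 "species": "mouse",
 "spine_rate": 1.63,
 "vesicle_count_mean": 220.0
}
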