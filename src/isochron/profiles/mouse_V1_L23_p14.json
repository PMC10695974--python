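{
 "age_days": 14,
 "axon_branch_rate": 0.12,
 "axon_synapse_rate": 0.71,
 "axons_per_soma_mean": 17.25,
 "bouton_volume_mean": 0.12,
 "excitatory_shaft_fraction": 0.23,
 "filopodia_rate": 0.075,
 "layer": "L23",
 "mito_density_mean": 19236.2,
 "mito_synapse_corr": 0.2,
 "name": "mouse_V1_L23_p14",
 "psd_logmean": 10.0,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.2,
 "soma_synapse_mean": 25.8,
 "species": "mouse",
 "spine_rate": 0.87,
 "vesicle_count_mean": 150.0
}
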