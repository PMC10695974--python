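{
 "age_days": 523,
 "axon_branch_rate": 0.15,
 "axon_synapse_rate": 0.86,
 "axons_per_soma_mean": 39.3,
 "bouton_volume_mean": 0.12,
 "excitatory_shaft_fraction": 0.24,
 "filopodia_rate": 0.002,
 "layer": "L23",
 "mito_density_mean": 32000.0,
 "mito_synapse_corr": 0.5,
 "name": "mouse_V1_L23_p523",
 "psd_logmean": 10.51,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.4,
 "soma_synapse_mean": 79.2,
 "species": "mouse",
 "spine_rate": 1.5,
 "vesicle_count_mean": 274.0
}
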