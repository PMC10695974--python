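{
 "age_days": 6,
 "axon_branch_rate": 0.09,
 "axon_synapse_rate": 1.09,
 "axons_per_soma_mean": 1.2,
 "bouton_volume_mean": 0.1,
 "excitatory_shaft_fraction": 0.24,
 "filopodia_rate": 0.71,
 "layer": "L23",
 "mito_density_mean": 10000.0,
 "mito_synapse_corr": 0.0,
 "name": "mouse_V1_L23_p6",
 "psd_logmean": 9.6,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.064,
 "soma_synapse_mean": 1.2,
 "species": "mouse",
 "spine_rate": 0.01,
 "vesicle_count_mean": 27.4
}
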