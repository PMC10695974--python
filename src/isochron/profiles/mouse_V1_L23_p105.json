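{
 "age_days": 105,
 "axon_branch_rate": 0.22,
 "axon_synapse_rate": 1.2,
 "axons_per_soma_mean": 33.0,
 "bouton_volume_mean": 0.12,
 "excitatory_shaft_fraction": 0.26,
 "filopodia_rate": 0.005,
 "layer": "L23",
 "mito_density_mean": 32072.9,
 "mito_synapse_corr": 0.54,
 "name": "mouse_V1_L23_p105",
 "psd_logmean": 10.51,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.35,
 "soma_synapse_mean": 72.2,
 "species": "mouse",
 "spine_rate": 2.1,
 "vesicle_count_mean": 274.0
}
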