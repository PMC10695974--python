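{
 "age_days": 7,
 "axon_branch_rate": 0.16,
 "axon_synapse_rate": 0.93,
 "axons_per_soma_mean": 13.3,
 "bouton_volume_mean": 0.08,
 "excitatory_shaft_fraction": 0.24,
 "filopodia_rate": 0.9,
 "layer": "L23",
 "mito_density_mean": 15000.0,
 "mito_synapse_corr": 0.2,
 "name": "primate_V1_L23_p7",
 "psd_logmean": 9.8,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.15,
 "soma_synapse_mean": 15.8,
 "species": "primate",
 "spine_rate": 0.31,
 "vesicle_count_mean": 30.0
}
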