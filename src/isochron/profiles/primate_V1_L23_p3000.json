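{
 "age_days": 3000,
 "axon_branch_rate": 0.22,
 "axon_synapse_rate": 0.46,
 "axons_per_soma_mean": 12.5,
 "bouton_volume_mean": 0.27,
 "excitatory_shaft_fraction": 0.26,
 "filopodia_rate": 0.005,
 "layer": "L23",
 "mito_density_mean": 30000.0,
 "mito_synapse_corr": 0.5,
 "name": "primate_V1_L23_p3000",
 "psd_logmean": 10.6,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.35,
 "soma_synapse_mean": 16.1,
 "species": "primate",
 "spine_rate": 0.86,
 "vesicle_count_mean": 274.0
}
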