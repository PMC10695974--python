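{
 "age_days": 75,
 "axon_branch_rate": 0.38,
 "axon_synapse_rate": 1.0,
 "axons_per_soma_mean": 22.4,
 "bouton_volume_mean": 0.16,
 "excitatory_shaft_fraction": 0.26,
 "filopodia_rate": 0.01,
 "layer": "L23",
 "mito_density_mean": 30000.0,
 "mito_synapse_corr": 0.5,
 "name": "primate_V1_L23_p75",
 "psd_logmean": 10.4,
 "psd_logsd": 0.8,
 "region": "V1",
 "shaft_rate": 0.3,
 "soma_synapse_mean": 50.3,
 "species": "primate",
 "spine_rate": 2.44,
 "vesicle_count_mean": 274.0
}
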