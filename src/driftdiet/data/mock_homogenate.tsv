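major_group	family	biomass_pct	sequence_pct	rcf_published
Fish	Acipenseridae	8.68	15.49	1.928
Fish	Catostomidae	7.18	3.72	0.499
Fish	Centrarchidae	6.77	7.0	1.037
Insects	Ephemerellidae	3.1	3.02	0.973
Insects	Isonychiidae/Siphlonuridae/Heptageniidae	21.79	39.8	2.373
Insects	Hydropsychidae/Leptoceridae	14.72	8.02	0.505
Insects	Chironomidae	1.03	1.6	1.548
Insects	Elmidae	7.3	0.96	0.123
Insects	Perlidae	7.49	0.87	0.108
Insects	Gomphidae	8.88	0.09	0.009
Crustaceans	Cambaridae	6.42	19.34	3.495
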