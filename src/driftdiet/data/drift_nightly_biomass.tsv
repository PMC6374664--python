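night	period	family	esu	individual_dry_mass_mg	biomass_g
2015-05-23	drift	Catostomidae	Catostomidae	1.193	8.42
2015-05-23	drift	Acipenseridae	Acipenseridae	8.5	1.65
2015-05-23	drift	Heptageniidae	Other Ephemeroptera	1.768	1.03
2015-05-23	drift	Baetidae	Baetidae	0.366	0
2015-05-23	drift	Ephemerellidae	Ephemerelloidea	1.255	0.15
2015-05-23	drift	Isonychiidae	Other Ephemeroptera	4.145	2.98
2015-05-23	drift	Siphlonuridae	Other Ephemeroptera	6.829	0
2015-05-23	drift	Ephemeridae	Other Ephemeroptera	5.578	0
2015-05-23	drift	Brachycentridae	Trichoptera	1.458	0
2015-05-23	drift	Glossosomatidae	Trichoptera	6.948	0
2015-05-23	drift	Helicopsychidae	Trichoptera	0.914	0.02
2015-06-04	drift	Catostomidae	Catostomidae	1.193	1.89
2015-06-04	drift	Acipenseridae	Acipenseridae	8.5	4.71
2015-06-04	drift	Heptageniidae	Other Ephemeroptera	1.768	0.74
2015-06-04	drift	Baetidae	Baetidae	0.366	0.02
2015-06-04	drift	Ephemerellidae	Ephemerelloidea	1.255	0.18
2015-06-04	drift	Isonychiidae	Other Ephemeroptera	4.145	2.98
2015-06-04	drift	Siphlonuridae	Other Ephemeroptera	6.829	0
2015-06-04	drift	Ephemeridae	Other Ephemeroptera	5.578	0
2015-06-04	drift	Brachycentridae	Trichoptera	1.458	0
2015-06-04	drift	Glossosomatidae	Trichoptera	6.948	0
2015-06-04	drift	Helicopsychidae	Trichoptera	0.914	0
2015-06-05	drift	Catostomidae	Catostomidae	1.193	3.53
2015-06-05	drift	Acipenseridae	Acipenseridae	8.5	2.21
2015-06-05	drift	Heptageniidae	Other Ephemeroptera	1.768	0.57
2015-06-05	drift	Baetidae	Baetidae	0.366	0.02
2015-06-05	drift	Ephemerellidae	Ephemerelloidea	1.255	0.08
2015-06-05	drift	Isonychiidae	Other Ephemeroptera	4.145	0.5
2015-06-05	drift	Siphlonuridae	Other Ephemeroptera	6.829	0.14
2015-06-05	drift	Ephemeridae	Other Ephemeroptera	5.578	0
2015-06-05	drift	Brachycentridae	Trichoptera	1.458	0
2015-06-05	drift	Glossosomatidae	Trichoptera	6.948	0.14
2015-06-05	drift	Helicopsychidae	Trichoptera	0.914	0.53
2015-06-06	drift	Catostomidae	Catostomidae	1.193	36.7
2015-06-06	drift	Acipenseridae	Acipenseridae	8.5	0.66
2015-06-06	drift	Heptageniidae	Other Ephemeroptera	1.768	0.46
2015-06-06	drift	Baetidae	Baetidae	0.366	0.05
2015-06-06	drift	Ephemerellidae	Ephemerelloidea	1.255	0.18
2015-06-06	drift	Isonychiidae	Other Ephemeroptera	4.145	0.08
2015-06-06	drift	Siphlonuridae	Other Ephemeroptera	6.829	0.14
2015-06-06	drift	Ephemeridae	Other Ephemeroptera	5.578	0.11
2015-06-06	drift	Brachycentridae	Trichoptera	1.458	0
2015-06-06	drift	Glossosomatidae	Trichoptera	6.948	0.14
2015-06-06	drift	Helicopsychidae	Trichoptera	0.914	0.02
2015-06-07	drift	Catostomidae	Catostomidae	1.193	7.9
2015-06-07	drift	Acipenseridae	Acipenseridae	8.5	0.12
2015-06-07	drift	Heptageniidae	Other Ephemeroptera	1.768	0.57
2015-06-07	drift	Baetidae	Baetidae	0.366	0.01
2015-06-07	drift	Ephemerellidae	Ephemerelloidea	1.255	0.13
2015-06-07	drift	Isonychiidae	Other Ephemeroptera	4.145	0.33
2015-06-07	drift	Siphlonuridae	Other Ephemeroptera	6.829	0
2015-06-07	drift	Ephemeridae	Other Ephemeroptera	5.578	0
2015-06-07	drift	Brachycentridae	Trichoptera	1.458	0.03
2015-06-07	drift	Glossosomatidae	Trichoptera	6.948	0.14
2015-06-07	drift	Helicopsychidae	Trichoptera	0.914	0
2015-07-03	postdrift	Catostomidae	Catostomidae	1.193	0.67
2015-07-03	postdrift	Acipenseridae	Acipenseridae	8.5	0
2015-07-03	postdrift	Heptageniidae	Other Ephemeroptera	1.768	0.18
2015-07-03	postdrift	Baetidae	Baetidae	0.366	0.14
2015-07-03	postdrift	Ephemerellidae	Ephemerelloidea	1.255	0
2015-07-03	postdrift	Isonychiidae	Other Ephemeroptera	4.145	0.33
2015-07-03	postdrift	Siphlonuridae	Other Ephemeroptera	6.829	0
2015-07-03	postdrift	Ephemeridae	Other Ephemeroptera	5.578	0
2015-07-03	postdrift	Brachycentridae	Trichoptera	1.458	0.26
2015-07-03	postdrift	Glossosomatidae	Trichoptera	6.948	0
2015-07-03	postdrift	Helicopsychidae	Trichoptera	0.914	0
2015-07-05	postdrift	Catostomidae	Catostomidae	1.193	0.84
2015-07-05	postdrift	Acipenseridae	Acipenseridae	8.5	0
2015-07-05	postdrift	Heptageniidae	Other Ephemeroptera	1.768	0.53
2015-07-05	postdrift	Baetidae	Baetidae	0.366	0.07
2015-07-05	postdrift	Ephemerellidae	Ephemerelloidea	1.255	0.03
2015-07-05	postdrift	Isonychiidae	Other Ephemeroptera	4.145	0.58
2015-07-05	postdrift	Siphlonuridae	Other Ephemeroptera	6.829	0
2015-07-05	postdrift	Ephemeridae	Other Ephemeroptera	5.578	0
2015-07-05	postdrift	Brachycentridae	Trichoptera	1.458	0.12
2015-07-05	postdrift	Glossosomatidae	Trichoptera	6.948	0
2015-07-05	postdrift	Helicopsychidae	Trichoptera	0.914	0
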