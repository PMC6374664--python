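species_a	species_b	alpha_drift	alpha_postdrift
BSD	BUR	0.30	0.14
BSD	CMM	0.11	0.19
BUR	CMM	0.31	0.31
BSD	CMS	0.04	0.22
BUR	CMS	0.19	0.14
CMM	CMS	0.48	0.19
BSD	CRC	0.27	0.23
BUR	CRC	0.41	0.49
CMM	CRC	0.16	0.20
CMS	CRC	0.23	0.20
BSD	HHC	0.25	0.36
BUR	HHC	0.53	0.35
CMM	HHC	0.36	0.50
CMS	HHC	0.19	0.24
CRC	HHC	0.44	0.49
BSD	LOP	0.24	0.36
BUR	LOP	0.46	0.27
CMM	LOP	0.18	0.24
CMS	LOP	0.05	0.16
CRC	LOP	0.26	0.24
HHC	LOP	0.38	0.38
BSD	PUS	0.17	0.12
BUR	PUS	0.10	0.09
CMM	PUS	0.28	0.20
CMS	PUS	0.01	0.07
CRC	PUS	0.11	0.10
HHC	PUS	0.27	0.10
LOP	PUS	0.10	0.23
BSD	RAD	0.37	0.42
BUR	RAD	0.51	0.23
CMM	RAD	0.23	0.26
CMS	RAD	0.06	0.37
CRC	RAD	0.29	0.23
HHC	RAD	0.44	0.25
LOP	RAD	0.79	0.36
PUS	RAD	0.23	0.26
BSD	ROB	0.33	0.15
BUR	ROB	0.55	0.33
CMM	ROB	0.30	0.15
CMS	ROB	0.05	0.22
CRC	ROB	0.26	0.16
HHC	ROB	0.38	0.18
LOP	ROB	0.49	0.49
PUS	ROB	0.32	0.39
RAD	ROB	0.65	0.35
BSD	SMB	0.33	0.16
BUR	SMB	0.45	0.21
CMM	SMB	0.23	0.04
CMS	SMB	0.03	0.13
CRC	SMB	0.22	0.06
HHC	SMB	0.38	0.02
LOP	SMB	0.47	0.39
PUS	SMB	0.45	0.06
RAD	SMB	0.61	0.21
ROB	SMB	0.61	0.40
BSD	WHS	0.12	0.07
BUR	WHS	0.33	0.39
CMM	WHS	0.43	0.31
CMS	WHS	0.30	0.05
CRC	WHS	0.32	0.40
HHC	WHS	0.40	0.28
LOP	WHS	0.15	0.17
PUS	WHS	0.11	0.42
RAD	WHS	0.18	0.22
ROB	WHS	0.17	0.32
SMB	WHS	0.17	0.14
BSD	YEP	0.25	0.28
BUR	YEP	0.28	0.26
CMM	YEP	0.36	0.36
CMS	YEP	0.17	0.25
CRC	YEP	0.20	0.17
HHC	YEP	0.51	0.22
LOP	YEP	0.27	0.34
PUS	YEP	0.45	0.19
RAD	YEP	0.41	0.43
ROB	YEP	0.36	0.36
SMB	YEP	0.63	0.36
WHS	YEP	0.32	0.17
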