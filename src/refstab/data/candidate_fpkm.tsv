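gene	CK	PEG	COLD	SALT
18S	702.31	619.06	650.75	642.99
ACT101	343.95	343.4	395.6	321.39
ACTB	29.9	28.47	21.23	20.88
ACT7	409.7	433.17	541.08	414.85
ACT11	178.49	168.43	192.51	164.35
TUA	204.66	175.09	156.08	156.78
TUB	169	135.68	129.07	121.21
GAPDH1	403.17	386.48	276.76	346.27
GAPDH2	1094.27	1141.33	968.64	1140.51
MET	1976.38	1789.19	2507.53	2023.19
FBA	1479.71	1708.19	1020.81	1267.67
HIS	654.76	620.72	509.92	616.37
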