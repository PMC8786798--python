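gene_a	gene_b	ka	ks	ka_ks	selection	t_mya
BdTLPK1	BdTLPK2	0.1102	1.0810	0.1020	Purifying	83.2
OsTLP5	OsTLP7	0.1014	0.6788	0.1494	Purifying	52.2
OsTLP22	OsTLP24	0.0697	0.4134	0.3190	Purifying	27.7
OsTLP23	OsTLP25	0.1149	0.3603	0.31646	Purifying	29.4
OsTLP26	OsTLP27	0.1569	1.3980	0.1122	Purifying	107.6
SbTLP28	SbTLP29	0.0911	0.6808	0.1338	Purifying	52.4
SbTLP31	SbTLP34	0.1388	1.7816	0.0779	Purifying	137
SbTLP32	SbTLP33	0.0055	0.0716	0.0771	Purifying	5.5
TaTLP1-A	TaTLP24-D	0.1224	0.8739	0.1401	Purifying	67.2
TaTLP1-B	TaTLP24-B	0.0937	0.8163	0.1148	Purifying	62.8
TaTLP12-B	TaTLP13-D	0.1193	1.1836	0.1008	Purifying	91
TaTLP15-A	TaTLP18-B	0.1368	0.9879	0.1384	Purifying	76
TaTLP15-B2	TaTLP18-A	0.1423	0.9582	0.1486	Purifying	73.7
TaTLP16-A	TaTLP17-A	0.1456	1.2825	0.1135	Purifying	98.7
ZmTLP1	ZmTLP35	0.0955	0.3929	0.2431	Purifying	30.2
ZmTLP2	ZmTLP34	0.1044	0.8149	0.1281	Purifying	62.7
ZmTLP3	ZmTLP22	0.0495	0.3036	0.1630	Purifying	23.4
ZmTLP9	ZmTLP12	0.0767	0.3783	0.2027	Purifying	29.1
ZmTLP13	ZmTLP37	0.0523	0.3200	0.1634	Purifying	24.7
ZmTLP16	ZmTLP33	0.0133	0.0141	0.9483	Purifying	1.1
ZmTLP20	ZmTLP25	0.0797	0.0889	0.8965	Purifying	6.9
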