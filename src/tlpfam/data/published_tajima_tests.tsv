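group_a	group_b	outgroup	nt	na	nb	chi2	p
BdTLP1	BdTLP2	BdTLP11	403	47	42	0.28	0.59611
OsTLP5	OsTLP7	OsTLP18	401	28	29	0.02	0.89463
OsTLP22	OsTLP24	OsTLP18	333	15	17	0.13	0.72367
OsTLP23	OsTLP25	OsTLP18	313	20	27	1.04	0.30723
OsTLP26	OsTLP27	OsTLP18	411	34	34	0	1
SbTLP28	SbTLP29	SbTLP5	316	19	30	2.47	0.11608
SbTLP31	SbTLP34	SbTLP5	312	27	32	0.42	0.51508
SbTLP32	SbTLP33	SbTLP5	347	2	2	0	1
TaTLP1-A	TaTLP24-D	TaTLP4-D	483	37	30	0.73	0.39245
TaTLP1-B	TaTLP24-B	TaTLP4-D	486	36	31	0.37	0.5413
TaTLP12-B	TaTLP13-D	TaTLP4-D	321	24	33	1.42	0.23323
TaTLP15-A	TaTLP18-B	TaTLP4-D	391	36	38	0.05	0.81615
TaTLP15-B2	TaTLP18-A	TaTLP4-D	260	28	27	0.02	0.89274
TaTLP16-A	TaTLP17-A	TaTLP4-D	291	36	31	0.37	0.5413
ZmTLP1	ZmTLP35	ZmTLP28	551	36	33	0.13	0.71798
ZmTLP2	ZmTLP34	ZmTLP28	541	34	25	1.37	0.24132
ZmTLP3	ZmTLP22	ZmTLP28	560	11	14	0.36	0.54851
ZmTLP9	ZmTLP12	ZmTLP28	372	6	12	2	0.1573
ZmTLP13	ZmTLP37	ZmTLP28	464	19	22	0.22	0.63941
ZmTLP16	ZmTLP33	ZmTLP28	551	5	7	0.33	0.5637
ZmTLP20	ZmTLP25	ZmTLP28	525	17	23	0.9	0.34278
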