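scale	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydrophobicity_kyte_doolittle	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
hydrophobicity_fauchere_pliska	0.31	1.54	-0.77	-0.64	1.79	0.0	0.13	1.80	-0.99	1.70	1.23	-0.60	0.72	-0.22	-1.01	-0.04	0.26	1.22	2.25	0.96
hydrophilicity_hopp_woods	-0.5	-1.0	3.0	3.0	-2.5	0.0	-0.5	-1.8	3.0	-1.8	-1.3	0.2	0.0	0.2	3.0	0.3	-0.4	-1.5	-3.4	-2.3
net_charge_index	0.0	0.0	-1.0	-1.0	0.0	0.0	0.1	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
polarity_grantham	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2
polarity_zimmerman	0.00	1.48	49.70	49.90	0.35	0.00	51.60	0.13	49.50	0.13	1.43	3.38	1.58	3.53	52.00	1.67	1.66	0.13	2.10	1.61
polarizability_charton	0.046	0.128	0.105	0.151	0.290	0.000	0.230	0.186	0.219	0.186	0.221	0.134	0.131	0.180	0.291	0.062	0.108	0.140	0.409	0.298
solvent_accessible_surface_area	1.181	1.461	1.587	1.862	2.228	0.881	2.025	1.810	2.258	1.931	2.034	1.655	1.468	1.932	2.560	1.298	1.525	1.645	2.663	2.368
side_chain_volume	27.5	44.6	40.0	62.0	115.5	0.0	79.0	93.5	100.0	93.5	94.1	58.7	41.9	80.7	105.0	29.3	51.3	71.5	145.5	117.3
flexibility_bhaskaran_ponnuswamy	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420
accessibility_janin	6.6	0.9	7.7	5.7	2.4	6.7	2.5	2.8	10.3	4.8	1.0	6.7	4.8	5.2	4.5	9.4	7.0	4.5	1.4	5.1
exposed_surface_chothia	115	135	150	190	210	75	195	175	200	170	185	160	145	180	225	115	140	155	255	230
turn_propensity_chou_fasman	0.66	1.19	1.46	0.74	0.60	1.56	0.95	0.47	1.01	0.59	0.60	1.56	1.52	0.98	0.95	1.43	0.96	0.50	0.96	1.14
antigenic_propensity_welling	0.115	-0.120	0.065	-0.071	0.212	-0.184	0.312	-0.292	0.206	0.075	-0.385	-0.077	-0.053	-0.011	0.058	-0.026	-0.045	-0.013	-0.114	0.013
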