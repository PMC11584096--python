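aa	zimmerman_polarity	average_flexibility	dayhoff_mutability	average_buried_area	doolittle_hydropathicity	atomic_weight_ratio	molecular_weight	bulkiness	tm_tendency
A	0.00	0.357	100	86.6	1.8	0.00	89.09	11.50	0.38
C	1.48	0.346	20	132.3	2.5	2.75	121.16	13.46	-0.30
D	49.70	0.511	106	97.8	-3.5	1.38	133.10	11.68	-3.27
E	49.90	0.497	102	113.9	-3.5	0.92	147.13	13.57	-2.90
F	0.35	0.314	41	194.1	2.8	0.00	165.19	19.80	1.98
G	0.00	0.544	49	62.9	-0.4	0.74	75.07	3.40	-0.19
H	51.60	0.323	66	155.8	-3.2	0.58	155.16	13.69	-1.44
I	0.13	0.462	96	158.0	4.5	0.00	131.17	21.40	1.97
K	49.50	0.466	56	115.5	-3.9	0.33	146.19	15.71	-3.46
L	0.30	0.365	40	164.1	3.8	0.00	131.17	21.40	1.82
M	1.43	0.295	94	172.9	1.9	0.00	149.21	16.25	1.40
N	3.38	0.463	134	103.3	-3.5	1.33	132.12	12.82	-1.62
P	1.58	0.509	56	92.9	-1.6	0.39	115.13	17.43	-1.44
Q	3.53	0.493	93	119.2	-3.5	0.89	146.15	14.45	-1.84
R	52.00	0.529	65	162.2	-4.5	0.65	174.20	14.28	-2.57
S	1.67	0.507	120	85.6	-0.8	1.42	105.09	9.47	-0.53
T	1.66	0.444	97	106.5	-0.7	0.71	119.12	15.77	-0.32
V	0.13	0.386	74	141.0	4.2	0.00	117.15	21.57	1.46
W	2.10	0.305	18	224.6	-0.9	0.13	204.23	21.67	1.53
Y	1.61	0.420	41	177.7	-1.3	0.20	181.19	18.03	0.49
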