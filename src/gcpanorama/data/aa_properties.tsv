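aa	molecular_weight	vdw_volume	isoelectric_point	hydrophobicity	polarity	n_atoms	nc_ratio
A	89.09	67	6.00	1.8	8.1	1	0.3333
R	174.20	148	10.76	-4.5	10.5	4	0.6667
N	132.12	96	5.41	-3.5	11.6	2	0.5000
D	133.10	91	2.77	-3.5	13.0	1	0.2500
C	121.16	86	5.07	2.5	5.5	1	0.3333
E	147.13	109	3.22	-3.5	12.3	1	0.2000
Q	146.15	114	5.65	-3.5	10.5	2	0.4000
G	75.07	48	5.97	-0.4	9.0	1	0.5000
H	155.15	118	7.59	-3.2	10.4	3	0.5000
I	131.17	124	6.02	4.5	5.2	1	0.1667
L	131.17	124	5.98	3.8	4.9	1	0.1667
K	146.19	135	9.74	-3.9	11.3	2	0.3333
M	149.21	124	5.74	1.9	5.7	1	0.2000
F	165.19	135	5.48	2.8	5.2	1	0.1111
P	115.13	90	6.30	-1.6	8.0	1	0.2000
S	105.09	73	5.68	-0.8	9.2	1	0.3333
T	119.12	93	5.60	-0.7	8.6	1	0.2500
W	204.23	163	5.89	-0.9	5.4	2	0.1818
Y	181.19	141	5.66	-1.3	6.2	1	0.1111
V	117.15	105	5.96	4.2	5.9	1	0.2000
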