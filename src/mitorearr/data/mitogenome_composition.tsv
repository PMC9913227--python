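# Published per-region nucleotide composition (percent) and skews of the two
# snake-eel mitogenomes (GenBank OM421636 / OP154196), as printed.
region	species	A	T	G	C	A_T	AT_skew	GC_skew
tRNAs	Ophichthus evermanni	30.93	24.63	20.13	24.31	55.56	0.113	-0.094
tRNAs	Ophichthus erabo	31.60	24.81	19.68	23.91	56.41	0.120	-0.097
rRNAs	Ophichthus evermanni	35.73	20.14	19.68	24.46	55.86	0.279	-0.108
rRNAs	Ophichthus erabo	36.83	19.72	19.57	23.88	56.55	0.303	-0.099
CRs	Ophichthus evermanni	31.75	31.85	15.69	20.71	63.59	-0.002	-0.138
CRs	Ophichthus erabo	36.45	27.36	15.08	21.12	63.80	0.142	-0.167
ND1	Ophichthus evermanni	27.04	26.42	15.79	30.75	53.46	0.012	-0.321
ND1	Ophichthus erabo	26.21	26.73	17.54	29.51	52.94	-0.010	-0.254
ND2	Ophichthus evermanni	34.56	24.27	12.65	28.52	58.83	0.175	-0.385
ND2	Ophichthus erabo	34.34	24.60	13.25	27.81	58.94	0.165	-0.355
COI	Ophichthus evermanni	27.54	28.34	18.22	25.90	55.88	-0.014	-0.174
COI	Ophichthus erabo	27.48	28.40	18.46	25.66	55.88	-0.016	-0.163
COII	Ophichthus evermanni	29.23	28.80	16.79	25.18	58.03	0.007	-0.200
COII	Ophichthus erabo	31.11	27.06	15.48	26.34	58.18	0.070	-0.260
ATP8	Ophichthus evermanni	35.12	25.60	11.31	27.98	60.71	0.157	-0.424
ATP8	Ophichthus erabo	36.31	27.38	8.33	27.98	63.69	0.140	-0.541
ATP6	Ophichthus evermanni	29.28	30.60	12.15	27.96	59.88	-0.022	-0.394
ATP6	Ophichthus erabo	28.95	27.63	12.57	30.85	56.58	0.023	-0.421
COIII	Ophichthus evermanni	27.35	27.48	17.56	27.61	54.83	-0.002	-0.222
COIII	Ophichthus erabo	27.35	26.59	18.45	27.61	53.94	0.014	-0.199
ND3	Ophichthus evermanni	28.37	30.37	13.47	27.79	58.74	-0.034	-0.347
ND3	Ophichthus erabo	24.36	32.95	16.05	26.65	57.31	-0.150	-0.248
ND4L	Ophichthus evermanni	28.62	27.27	13.80	30.30	55.89	0.024	-0.374
ND4L	Ophichthus erabo	27.61	27.95	13.80	30.64	55.56	-0.006	-0.379
ND4	Ophichthus evermanni	30.27	27.52	14.12	28.10	57.78	0.048	-0.331
ND4	Ophichthus erabo	30.99	26.72	13.61	28.67	57.71	0.074	-0.356
ND5	Ophichthus evermanni	31.81	26.96	13.56	27.67	58.77	0.083	-0.342
ND5	Ophichthus erabo	33.33	26.25	13.34	27.07	59.59	0.119	-0.340
Cytb	Ophichthus evermanni	39.50	14.26	14.07	32.18	53.76	0.469	-0.392
Cytb	Ophichthus erabo	28.07	28.68	16.40	26.84	56.75	-0.011	-0.241
ND6	Ophichthus evermanni	29.42	30.56	14.80	25.22	59.98	-0.019	-0.260
ND6	Ophichthus erabo	40.66	12.91	13.49	32.95	53.56	0.518	-0.419
PCGs	Ophichthus evermanni	30.23	27.17	14.89	27.71	57.40	0.053	-0.301
PCGs	Ophichthus erabo	30.34	26.56	15.21	27.89	56.90	0.066	-0.294
pos1	Ophichthus evermanni	29.61	28.43	14.89	27.08	58.04	0.020	-0.290
pos1	Ophichthus erabo	30.34	24.71	18.07	26.88	55.05	0.102	-0.196
pos2	Ophichthus evermanni	30.44	28.46	13.07	28.02	58.90	0.034	-0.364
pos2	Ophichthus erabo	26.84	31.72	14.51	26.94	58.56	-0.083	-0.299
pos3	Ophichthus evermanni	30.64	24.62	16.70	28.04	55.26	0.109	-0.253
pos3	Ophichthus erabo	33.90	23.21	13.01	29.87	57.11	0.187	-0.393
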