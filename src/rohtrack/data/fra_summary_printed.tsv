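name	chromosome	band	rohf_nci60	rohf_hapmap	rohf_diff	n_mirna_5mb	n_mirna_1mb
FRA1C	1	1p31.2	0.56	0.28	0.28	5	0
FRA2F	2	2q21.3	0.57	0.52	0.05	3	1
FRA4C	4	4q31.1	0.55	0.15	0.40	2	0
FRA5C	5	5q31.1	0.53	0.36	0.17	4	1
FRA5F	5	5q21	0.53	0.34	0.19	5	0
FRA7G	7	7q31.2	0.56	0.47	0.09	1	0
FRA9B	9	9q32	0.51	0.09	0.42	3	0
FRA9E	9	9q32	0.51	0.09	0.42	3	0
FRA9A	9	9p21	0.75	0.24	0.51	2	0
FRA9C	9	9p21	0.75	0.24	0.51	2	0
FRA10C	10	10q21	0.54	0.22	0.31	2	0
FRA10D	10	10q22.1	0.56	0.27	0.29	2	0
FRA10A	10	10q23.3	0.59	0.28	0.31	3	0
FRA11B	11	11q23.3	0.58	0.27	0.31	3	0
FRA11F	11	11q14.2	0.58	0.27	0.31	2	0
FRA11G	11	11q23.3	0.58	0.27	0.31	3	0
FRA12B	12	12q21.3	0.59	0.37	0.21	0	0
FRA13A	13	13q13.2	0.56	0.11	0.45	0	0
FRA13B	13	13q21	0.58	0.10	0.48	0	0
FRA13D	13	13q32	0.59	0.10	0.49	9	0
FRA13C	13	13q21.2	0.67	0.17	0.50	1	0
FRA14B	14	14q23	0.71	0.47	0.24	2	0
FRA14C	14	14q24.1	0.74	0.65	0.10	2	0
FRA16B	16	16q22.1	0.57	0.29	0.27	5	1
FRA16C	16	16q22.1	0.57	0.29	0.27	5	1
FRA17A	17	17p12	0.61	0.06	0.55	5	0
FRA17B	17	17q23.1	0.65	0.30	0.36	6	3
FRA18A	18	18q12.2	0.55	0.28	0.27	4	1
FRA22B	22	22q12.2	0.54	0.18	0.36	7	2
FRA22A	22	22q13	0.56	0.07	0.49	8	1
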