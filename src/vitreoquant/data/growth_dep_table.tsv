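accession	protein_name	gene	fc_od_14	fc_os_14	ave_14	sd_14	fc_od_21	fc_os_21	ave_21	sd_21	fc_od_28	fc_os_28	ave_28	sd_28
R4GLH0	IGFBP N-terminal domain-containing protein	ESM1	4.08	3.02	3.55	0.75	4.53	3.51	4.02	0.72	6.73	5.09	5.91	1.16
Q4ADJ6	Ovotransferrin	TFEW	4.09	2.3	3.2	1.27	1.81	2.26	2.04	0.32	9.39	5.11	7.25	3.03
P84407	Alpha-fetoprotein	AFP	0.01	0.4	0.21	0.28	0.01	0.01	0.01	0.00	0.01	0.02	0.02	0.01
P79995	Cadherin-10	CDH10	0.46	0.12	0.29	0.24	0.43	0.39	0.41	0.03	0.4	0.35	0.38	0.04
P24503	Cadherin-4	CDH4	0.31	0.32	0.32	0.01	0.34	0.43	0.39	0.06	0.37	0.4	0.39	0.02
E1C3A7	Cadherin 22	CDH22	0.41	0.14	0.28	0.19	0.34	0.41	0.38	0.05	0.33	0.3	0.32	0.02
Q8AWW2	Cadherin-7	N/A	0.33	0.38	0.36	0.04	0.39	0.32	0.36	0.05	0.32	0.34	0.33	0.01
Q8QGH3	Cadherin-20	CDH20	0.47	0.61	0.54	0.1	0.44	0.44	0.44	0.00	0.45	0.53	0.49	0.06
Q9W6E1	Neurocan core protein	N/A	0.23	0.48	0.36	0.18	0.21	0.2	0.21	0.01	0.17	0.19	0.18	0.01
Q90953	Versican core protein	VCAN	0.33	0.59	0.46	0.18	0.2	0.25	0.23	0.04	0.19	0.19	0.19	0.00
O93574	Reelin	RELN	0.41	0.58	0.5	0.12	0.45	0.48	0.47	0.02	0.42	0.47	0.45	0.04
F1NSJ1	Contactin-2	CNTN2	0.51	0.23	0.37	0.2	0.44	0.46	0.45	0.01	0.52	0.52	0.52	0.00
P35331	Neuronal cell adhesion molecule	NRCAM	0.32	0.57	0.45	0.18	0.59	0.56	0.58	0.02	0.67	0.5	0.59	0.12
Q90610	Neogenin	NEO1	0.65	0.39	0.52	0.18	0.54	0.55	0.55	0.00	0.67	0.62	0.65	0.04
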