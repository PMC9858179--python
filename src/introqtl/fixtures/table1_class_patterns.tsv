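class	ps_mean	mean_SC3-5-7	sig_SC3-5-7	mean_SC3-5-8	sig_SC3-5-8	mean_SC3-5-12	sig_SC3-5-12	mean_SC3-5-13	sig_SC3-5-13	mean_SC3-5-14	sig_SC3-5-14	interpretable
ACE	5.89	7.24	0	43.24	1	46.39	1	15.73	1	24.56	1	1
NAE	6.31	5.38	0	4.90	0	5.47	0	6.36	0	6.00	0	1
ALD	33.30	52.02	1	19.24	0	13.64	-1	35.82	0	29.44	0	1
ALC	16.80	17.17	0	14.78	0	11.40	0	15.54	0	16.05	0	1
KET	19.80	9.48	-1	6.79	-1	6.35	-1	13.00	-1	10.06	-1	1
ACD	0.24	0.38	0	0.36	0	0.30	0	0.23	0	1.02	0	1
SDC	1.50	2.22	0	7.79	1	7.25	1	4.84	1	6.99	1	1
TER	1.40	1.01	0	0.73	-1	0.97	0	1.36	0	1.31	0	1
AHA	2.08	1.69	0	0.58	-1	1.20	0	1.96	0	1.27	0	1
OTH	6.42	3.51	0	1.63	-1	2.62	-1	4.36	0	3.36	-1	0
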