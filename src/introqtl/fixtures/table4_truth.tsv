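order	cas	direction	colocalizes_roi	ethylene
1	000554-12-1	1	1	1
2	000108-21-4	1	1	1
3	001534-08-3	1	0	-1
5	000623-42-7	1	1	1
6	000137-32-6	1	1	1
7	000110-19-0	1	1	1
8	000868-57-5	1	0	-1
10	000106-36-5	1	1	1
11	000123-86-4	1	1	1
12	002432-51-1	1	1	1
13	000123-92-2	1	1	1
14	000624-41-9	1	0	-1
15	000100-42-5	-1	1	1
16	016630-66-3	1	1	1
17	001191-16-8	1	0	-1
18	023747-45-7	1	1	1
20	115051-66-6	1	1	1
21	000142-92-7	1	0	-1
22	000470-82-6	1	1	1
24	NID1	1	1	1
26	000140-11-4	1	1	1
30	000103-45-7	1	0	-1
31	074367-33-2	-1	0	-1
39	000079-77-6	1	0	-1
41	000074-93-1	-1	0	-1
46	000123-72-8	-1	0	-1
49	000123-73-9	-1	0	-1
54	017528-72-2	-1	0	-1
57	000108-10-1	-1	1	1
58	068920-64-9	-1	0	-1
60	NID4	1	0	-1
61	000105-46-4	1	1	1
63	000820-71-3	1	1	1
64	000066-25-1	-1	0	-1
69	000816-11-5	1	0	-1
70	000540-42-1	1	1	1
72	000628-63-7	1	1	1
73	000591-23-1	-1	0	-1
76	000108-83-8	-1	0	-1
80	001193-81-3	-1	0	-1
81	001114-92-7 (meso)	1	0	-1
83	001114-92-7 (rac)	1	0	-1
89	000112-06-1	1	0	-1
110	74367-31-0	-1	0	-1
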