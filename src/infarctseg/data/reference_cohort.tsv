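patient	sex	age	demar_offset	vol_semi_ml	vol_auto_ml	delta_vol_pct	si_pct	kappa_pct	sen_pct	spe_pct	ppv_pct	npv_pct
1	M	73	0.27	0.155	0.212	36.6	84.661	84.661	100.000	99.999	73.529	100.000
2	M	80	0.19	0.358	0.377	5.3	97.438	97.438	100.000	100.000	95.014	100.000
3	F	69	0.21	0.399	0.381	-4.4	97.716	97.716	95.556	100.000	100.000	100.000
4	F	84	0.22	0.474	0.378	-20.3	86.835	86.834	78.037	100.000	98.349	99.998
5	F	70	0.20	0.501	0.337	-32.7	91.662	91.662	93.398	100.000	91.723	100.000
6	M	63	0.19	0.545	0.451	-17.2	90.413	90.412	82.764	100.000	100.000	99.999
7	M	55	0.20	0.612	0.471	-22.9	82.684	82.683	73.190	100.000	95.072	99.998
8	F	66	0.15	0.644	0.479	-25.6	85.332	85.331	74.436	100.000	100.000	99.998
9	M	61	0.21	0.796	0.895	12.5	94.143	94.142	100.000	99.999	88.938	100.000
10	M	64	0.19	1.003	1.019	1.6	98.927	98.927	99.710	100.000	98.171	100.000
11	F	75	0.25	1.675	1.794	7.1	94.373	94.372	97.619	99.998	91.568	99.999
12	F	56	0.19	1.966	1.497	-23.9	86.438	86.434	76.140	100.000	100.000	99.992
13	F	74	0.31	2.141	3.232	51.0	79.722	79.715	100.000	99.984	66.312	100.000
14	F	86	0.14	3.749	2.228	-40.6	74.359	74.349	59.444	100.000	100.000	99.977
15	M	76	0.19	4.143	3.448	-16.8	85.827	85.819	78.898	99.997	95.789	99.987
16	F	87	0.17	10.108	8.351	-17.4	90.453	90.440	82.621	100.000	100.000	99.975
17	F	83	0.16	12.657	10.088	-20.3	88.603	88.582	79.662	100.000	99.952	99.958
18	F	57	0.19	13.063	13.492	3.3	97.656	97.652	99.254	99.992	96.124	99.999
19	M	72	0.19	15.014	11.611	-22.7	87.181	87.159	77.332	100.000	99.992	99.955
20	M	80	0.24	46.828	54.497	16.4	92.426	92.374	99.990	99.894	85.933	100.000
21	M	74	0.22	56.517	59.147	4.7	97.526	97.503	99.793	99.956	95.365	99.998
22	M	91	0.10	482.939	429.534	-11.1	94.147	93.675	88.942	100.000	100.000	99.056
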