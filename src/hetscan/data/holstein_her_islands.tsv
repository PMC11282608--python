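chrom	start	end	n_snp	r2	pct_5_0	pct_5_1	pct_5_2	pct_10_0	pct_10_1	pct_10_2	pct_10_3	pct_10_4	pct_10_5
1	8947612	8984143	54	0.010	10.14	35.97	61.94	10.11	32.86	58.74	77.79	88.23	94.93
1	77541594	77574520	114	0.143	24.20	48.00	67.19	17.75	41.52	64.06	74.97	78.78	84.88
1	86455167	86476612	40	0.062	10.00	10.00	14.77	10.00	10.00	12.34	23.67	32.36	32.87
1	88572745	88595480	149	0.021	10.00	10.00	10.00	10.00	10.00	10.00	12.92	19.51	25.28
1	158026308	158204765	2064	0.173	46.31	75.37	87.27	18.18	45.38	70.30	85.03	91.26	93.40
2	11729	23106	13	0.001	10.00	10.95	26.02	10.00	10.95	26.02	43.45	55.63	63.23
2	121358897	121376671	23	0.010	33.05	56.62	70.09	17.84	41.76	62.04	73.44	76.09	75.48
3	119398854	119418253	22	0.004	34.63	56.51	71.32	24.38	49.64	69.09	80.00	78.71	76.62
4	114921	131012	29	0.001	11.17	40.27	70.22	11.17	40.27	70.22	88.15	94.99	98.03
4	7748093	7786109	61	0.001	39.61	68.96	83.21	27.85	55.59	73.49	83.41	88.04	92.01
4	108267668	108297255	35	0.004	28.34	57.05	64.85	21.52	50.88	63.06	72.90	82.38	90.95
5	79520323	79544963	23	0.002	39.11	71.75	89.56	28.25	57.91	80.25	91.35	96.19	98.20
6	39744	67663	32	0.003	32.00	46.50	69.91	17.76	31.63	60.84	84.15	95.38	95.93
6	8997519	9019722	29	0.014	19.78	38.10	56.98	19.57	37.63	56.89	71.05	83.75	89.99
7	9986201	9996885	10	0.133	53.60	84.25	91.97	10.22	28.68	48.38	69.13	81.96	90.93
7	104258582	104281037	14	0.001	49.34	79.67	92.09	24.80	55.07	80.54	92.39	95.66	97.55
8	4462538	4479090	20	0.001	38.93	60.33	70.98	19.52	44.73	63.41	78.73	90.41	96.83
8	111993409	112004112	16	0.001	14.86	39.06	66.67	14.86	37.75	64.39	85.79	96.15	88.00
9	104119378	104141024	13	0.002	29.58	63.91	84.23	10.32	35.01	64.23	84.81	95.70	98.46
10	18852596	18940485	99	0.101	23.20	63.54	75.32	14.38	49.14	75.32	89.89	96.52	98.24
10	23775405	24071948	47	0.009	67.00	87.97	88.53	42.16	72.19	88.53	94.83	96.73	97.42
10	24100254	24459318	44	0.001	68.02	88.26	88.46	43.29	72.75	88.46	94.40	96.17	96.98
10	42169769	42201656	32	0.002	29.98	57.85	74.20	20.15	50.29	74.20	79.39	74.09	76.30
12	21476167	21501639	42	0.006	25.52	49.65	66.89	21.92	45.33	63.26	77.92	84.18	89.73
13	11310352	11334273	40	0.028	22.71	44.06	58.87	21.32	42.72	58.24	70.72	77.30	81.55
13	43331311	43358950	22	0.003	15.59	51.88	81.02	10.29	37.05	67.87	86.79	95.53	96.96
14	13489163	13506285	13	0.001	47.68	74.43	90.80	21.87	56.03	81.83	81.15	89.10	95.45
15	7225	21935	40	0.002	13.54	40.19	65.25	13.05	39.08	64.56	79.05	72.18	63.03
15	12265252	12276097	11	0.002	33.28	68.21	88.58	21.58	57.92	82.08	93.63	66.95	77.78
15	51457087	51470355	15	0.002	10.00	30.59	54.46	10.00	28.37	52.39	65.55	76.03	81.23
17	68057715	68070742	11	0.001	32.07	52.70	71.96	16.49	39.07	63.25	81.00	92.69	88.78
17	71143576	71169181	36	0.001	36.07	59.83	78.10	27.79	56.11	77.38	90.09	95.91	97.75
18	63626958	63643160	17	0.001	22.49	38.40	58.38	22.49	38.40	58.38	83.92	84.09	90.50
19	31258759	31290592	27	0.002	10.00	12.64	21.25	10.00	10.66	20.16	33.49	48.13	61.26
19	43263869	43277164	10	0.001	19.34	53.57	79.55	10.00	21.47	56.75	81.73	91.62	94.29
21	58941106	58962580	11	0.007	20.53	49.73	68.81	10.00	30.53	55.44	76.78	87.90	91.34
21	69831448	69844336	18	0.039	29.53	63.65	84.69	18.87	51.74	78.87	91.47	91.19	93.04
22	8699801	8723909	18	0.001	12.38	40.16	65.00	10.00	25.38	53.58	76.12	85.55	89.24
23	21755400	21781579	23	0.191	31.61	54.95	75.63	25.04	40.82	63.21	86.17	94.46	95.79
23	30203633	30220658	20	0.001	36.33	73.85	89.66	21.46	57.35	81.93	91.83	94.93	96.25
23	30303856	30326074	25	0.001	19.08	49.33	71.44	13.90	36.24	62.50	81.51	89.13	93.70
24	22868170	22890804	36	0.035	26.95	47.28	63.89	18.59	38.13	59.57	68.92	80.36	85.13
26	15215724	15230752	13	0.001	32.61	43.57	84.13	15.28	43.57	71.63	88.80	95.25	97.08
26	50115341	50125621	11	0.015	10.00	24.67	55.64	10.00	24.67	53.02	78.12	83.11	85.62
28	16525956	16567307	16	0.001	44.52	66.83	79.83	28.34	55.69	76.22	89.45	93.82	95.44
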