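# Published reference values: group-mean expression (sFPKM) for the top 20 increasing and
# decreasing genes per male brain region in the rat ketamine infusion time course, with the
# printed pseudocount 10h/control expression ratio and BH-adjusted p-value.
region	gene	mean_Control	mean_1h	mean_10h	mean_Recovery	printed_ratio_10h_control	adj_p	direction
frontal_cortex	Maff	0.25	1.06	1.65	0.15	4.99	6.98e-06	up
frontal_cortex	Ret	1.1	1.07	5.14	1.32	4.37	8.89e-05	up
frontal_cortex	Crem	4.01	7.43	12.56	4.33	3.08	6.98e-06	up
frontal_cortex	S100a8	0.72	1.33	2.39	0.76	3.03	0.00402	up
frontal_cortex	Il6r	4.55	5.83	13.0	5.39	2.82	6.98e-06	up
frontal_cortex	Acer2	6.47	8.85	17.84	6.09	2.73	1.97e-05	up
frontal_cortex	Mt2A	33.73	32.01	89.62	24.49	2.65	1.38e-05	up
frontal_cortex	Fosl2	4.07	7.26	10.48	4.51	2.53	0.000186	up
frontal_cortex	Angpt2	1.03	1.14	2.72	0.69	2.49	3.94e-05	up
frontal_cortex	Slc4a11	2.89	4.24	7.27	3.09	2.46	0.00118	up
frontal_cortex	S100a9	1.59	1.47	3.99	1.22	2.42	0.000706	up
frontal_cortex	Ankdd1a	0.47	0.73	1.19	0.62	2.26	0.000228	up
frontal_cortex	Nfil3	1.48	2.36	3.43	1.43	2.23	6.98e-06	up
frontal_cortex	Tex15	0.63	0.78	1.52	0.79	2.22	0.00733	up
frontal_cortex	Hmgcs2	1.22	1.35	2.76	1.31	2.17	0.00773	up
frontal_cortex	Cfap70	4.05	4.61	8.72	4.92	2.12	3.06e-05	up
frontal_cortex	Rgs16	5.32	7.27	11.39	5.13	2.12	1.64e-05	up
frontal_cortex	Fosb	2.75	6.08	5.93	2.78	2.12	0.000732	up
frontal_cortex	Mc4r	0.92	1.35	2.04	1.2	2.1	0.0041	up
frontal_cortex	Upp1	3.2	3.68	6.82	3.41	2.1	0.000685	up
frontal_cortex	Egr2	2.92	1.67	0.4	2.86	0.16	0.00309	down
frontal_cortex	Egr1	50.58	33.52	10.36	65.14	0.21	1.64e-05	down
frontal_cortex	F2rl2	1.08	1.03	0.34	0.93	0.37	0.00849	down
frontal_cortex	Tslp	1.9	1.95	0.7	2.0	0.4	0.00546	down
frontal_cortex	Gypc	2.5	2.72	0.97	2.93	0.41	0.000171	down
frontal_cortex	Egr4	3.36	3.85	1.36	4.97	0.42	0.00546	down
frontal_cortex	Tnfaip3	3.96	4.04	1.67	4.02	0.43	0.000186	down
frontal_cortex	Sstr3	8.15	8.6	3.6	9.37	0.45	6.98e-06	down
frontal_cortex	Prkcdbp	9.51	10.75	4.29	13.33	0.46	5.71e-05	down
frontal_cortex	Kcnv1	41.09	37.86	19.0	46.38	0.46	2.92e-06	down
frontal_cortex	Trpm4	3.2	3.95	1.44	3.73	0.47	0.000109	down
frontal_cortex	Dact2	25.75	24.62	11.99	27.01	0.47	5.78e-05	down
frontal_cortex	Stard8	12.59	14.22	5.94	13.04	0.48	0.000602	down
frontal_cortex	Ptgs2	13.52	9.62	6.39	13.38	0.48	2.4e-05	down
frontal_cortex	Lrrc17	1.65	1.89	0.74	1.73	0.48	0.000787	down
frontal_cortex	Bace2	2.67	2.78	1.23	2.69	0.48	0.00313	down
frontal_cortex	Kcnh4	5.19	5.32	2.45	6.07	0.48	0.00015	down
frontal_cortex	Lor	1.34	1.35	0.6	1.7	0.49	1.39e-05	down
frontal_cortex	Lrrc75a	2.66	3.35	1.27	3.41	0.5	0.0015	down
frontal_cortex	Rara	5.26	6.22	2.57	5.59	0.5	0.000708	down
hippocampus	Ccl2	0.05	0.13	7.38	0.08	49.88	1.2e-08	up
hippocampus	Ccl7	0.07	0.03	4.66	0.03	28.48	2.3e-07	up
hippocampus	Maff	0.22	0.71	5.55	0.25	17.49	2.1e-12	up
hippocampus	FAM187A	0.11	0.38	1.89	0.36	9.27	0.00031	up
hippocampus	Atf3	0.06	0.36	1.13	0.05	7.77	2.9e-08	up
hippocampus	Lif	0.08	0.15	1.1	0.07	6.5	9.1e-10	up
hippocampus	Socs3	0.35	0.31	2.69	0.29	6.17	8.5e-11	up
hippocampus	Hmox1	3.74	3.53	22.43	2.99	5.86	2.1e-12	up
hippocampus	Angpt2	0.69	0.89	2.82	0.53	3.68	9.6e-09	up
hippocampus	Gem	1.33	1.42	5.08	1.77	3.61	5.7e-08	up
hippocampus	Cd44	7.42	7.06	25.35	6.27	3.38	1.4e-10	up
hippocampus	Acer2	5.57	6.42	18.28	4.98	3.24	2.7e-08	up
hippocampus	Cebpd	4.48	3.45	14.17	3.96	3.11	0.00019	up
hippocampus	Aspg	0.41	0.33	1.47	0.5	3.1	7e-05	up
hippocampus	Clcf1	0.7	0.88	2.29	0.6	2.99	1.4e-09	up
hippocampus	Mt2A	41.7	39.94	119.18	35.18	2.85	8.3e-10	up
hippocampus	Tnfrsf12a	2.01	2.17	5.89	1.57	2.85	1.8e-08	up
hippocampus	Smad6	0.29	0.45	1.0	0.26	2.85	6.9e-07	up
hippocampus	Hspb1	3.02	3.55	8.75	2.87	2.84	0.00018	up
hippocampus	Flnc	6.33	5.84	17.67	5.23	2.77	7.1e-09	up
hippocampus	Stra6	1.36	1.2	0.46	1.15	0.39	4.69e-05	down
hippocampus	Egr1	38.35	33.75	15.94	37.13	0.42	0.000235	down
hippocampus	Slc38a5	1.43	1.46	0.66	1.19	0.5	0.00276	down
hippocampus	Lrrc75a	2.57	2.57	1.3	2.07	0.52	7.85e-07	down
hippocampus	Ptgs2	16.97	16.27	9.13	15.55	0.54	5.74e-06	down
hippocampus	Cyp2j10	3.9	3.46	2.08	3.61	0.54	0.00711	down
hippocampus	Plekha2	6.95	6.8	3.73	5.39	0.54	0.00055	down
hippocampus	Car7	11.25	10.81	6.13	10.98	0.55	1.94e-06	down
hippocampus	Kcnv1	13.28	13.67	7.34	15.05	0.56	3.41e-06	down
hippocampus	Slc52a3	1.22	1.16	0.65	0.88	0.56	0.0098	down
hippocampus	Tnc	5.63	5.92	3.13	5.55	0.56	2e-05	down
hippocampus	Nxpe1	1.58	1.52	0.86	1.79	0.57	5.75e-05	down
hippocampus	Tie1	6.0	5.25	3.43	4.54	0.58	8.43e-06	down
hippocampus	Serpinb6b	0.9	0.55	0.48	1.09	0.58	0.000366	down
hippocampus	Gdpd2	1.86	1.16	1.06	1.67	0.59	0.00232	down
hippocampus	Kcnh4	2.33	2.43	1.36	2.5	0.6	0.000166	down
hippocampus	Rbm3	79.57	88.54	47.99	101.12	0.6	2.63e-06	down
hippocampus	Slc26a7	2.1	2.03	1.24	2.09	0.61	0.00106	down
hippocampus	Prom1	10.16	10.73	6.14	8.53	0.61	0.000249	down
hippocampus	Car4	15.59	15.16	9.46	15.04	0.61	0.00121	down
amygdala	Maff	0.31	0.92	2.56	0.41	6.52	1.5e-05	up
amygdala	S100a9	0.47	1.13	2.82	0.42	5.09	0.0032	up
amygdala	Inmt	0.3	0.66	1.69	0.13	4.47	0.0012	up
amygdala	Acer2	4.57	7.3	20.37	4.04	4.39	6.6e-07	up
amygdala	Aspg	0.27	0.25	1.45	0.5	4.25	0.001	up
amygdala	Ccl2	0.17	0.3	1.04	0.03	4.24	5.5e-05	up
amygdala	Crem	2.8	6.27	12.01	2.9	4.18	2.9e-06	up
amygdala	Ttr	4.24	3.79	17.78	3.56	4.12	0.0078	up
amygdala	Tmco4	0.62	0.64	2.74	0.53	3.96	1.1e-06	up
amygdala	S100a8	0.35	0.38	1.66	0.46	3.88	0.0039	up
amygdala	Spta1	0.35	0.26	1.57	0.3	3.69	0.00012	up
amygdala	Mt2A	19.48	19.51	64.71	20.03	3.31	9.9e-06	up
amygdala	Angpt2	1.13	1.29	3.92	0.52	3.28	7.4e-06	up
amygdala	Inhba	2.11	4.28	7.12	2.02	3.26	0.0068	up
amygdala	Ret	7.39	5.52	24.01	7.87	3.22	0.00042	up
amygdala	Smad6	0.29	0.46	1.12	0.25	3.09	2.7e-05	up
amygdala	Tmem82	0.27	0.23	1.0	0.24	2.95	0.00018	up
amygdala	Insrr	0.32	0.5	1.11	0.03	2.9	0.00091	up
amygdala	Hmox1	3.08	4.16	9.14	3.81	2.9	2.2e-05	up
amygdala	Lox	0.77	0.74	2.37	0.36	2.85	0.00058	up
amygdala	Stra6	1.18	1.09	0.41	0.8	0.4	0.0099	down
amygdala	Egr1	50.04	35.29	20.78	37.52	0.42	0.000649	down
amygdala	Klra1	1.23	1.18	0.51	1.17	0.46	0.00346	down
amygdala	Car7	5.65	7.48	3.11	5.63	0.56	3.58e-05	down
amygdala	Kcnv1	21.29	22.45	12.38	23.66	0.58	1.08e-06	down
amygdala	Egr2	2.65	2.68	1.55	2.18	0.6	0.000284	down
amygdala	Lsp1	1.68	1.39	0.98	2.16	0.61	0.000666	down
amygdala	Cd180	2.35	1.87	1.41	2.81	0.62	0.00194	down
amygdala	Trim54	20.42	21.96	12.63	19.98	0.62	0.000526	down
amygdala	Rnd1	21.32	24.33	13.57	22.64	0.64	0.000115	down
amygdala	Ciart	6.41	6.38	4.09	7.78	0.64	8.7e-05	down
amygdala	Zdhhc22	24.73	26.46	15.88	30.08	0.64	1.93e-05	down
amygdala	Oas1b	1.68	1.6	1.05	2.31	0.64	0.000304	down
amygdala	Gpr12	4.06	4.1	2.58	3.82	0.64	0.000284	down
amygdala	Fam180b	3.71	3.29	2.36	3.98	0.64	1.08e-06	down
amygdala	Tmem266	4.02	4.33	2.56	4.43	0.65	3.76e-06	down
amygdala	Pkp2	3.73	3.96	2.38	3.43	0.65	0.0036	down
amygdala	Rbm3	103.53	100.52	67.54	95.15	0.65	0.00215	down
amygdala	Lurap1	9.16	9.16	6.01	10.58	0.66	3.73e-07	down
amygdala	Mas1	4.81	6.2	3.16	4.98	0.66	2.36e-05	down
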