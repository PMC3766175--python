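mirna	mean_endo	sd_endo	cv_endo	maxmin_r_endo	mean_ctrl	sd_ctrl	cv_ctrl	maxmin_r_ctrl	mean_ratio	median_ratio	mean_fc	median_fc
hsa-miR-24	1.29	0.04	3.12	1.089	1.16	0.08	6.87	1.21	1.11	1.17	1.11	1.17
hsa-miR-885-5p	4.18	3.92	93.75	12.25	2.06	1.23	59.96	9.22	2.02	1.21	2.02	1.21
hsa-miR-26b	1.38	0.43	31.37	2.69	3.04	3.60	118.48	12.84	0.45	0.92	-2.19	-1.08
hsa-let-7b	1.002	0.32	32.48	3.11	1.37	0.39	28.64	2.352	0.730	0.870	-1.369	-1.149
hsa-miR-185	0.98	0.42	42.89	5.69	1.52	0.74	48.87	4.3	0.69	0.81	-1.54	-1.23
hsa-miR-142-3p	1.81	1.07	58.93	8.57	3.03	1.61	53.12	5.43	0.6	0.56	-1.66	-1.76
hsa-miR-29b	0.96	0.64	66.84	9.34	1.73	0.96	55.89	5.78	0.55	0.59	-1.79	-1.68
hsa-miR-483-5p	0.75	0.58	76.80	22.55	1.34	0.76	56.75	8.29	0.56	0.43	-1.77	-2.31
hsa-miR-144*	0.14	0.085	57.82	8.9	0.49	0.29	60.68	6.65	0.3	0.34	-3.31	-2.89
hsa-miR-145*	1.04	0.8	77.46	12.37	2.39	1.8	75.38	8.9	0.43	0.34	-2.3	-2.94
hsa-miR-629*	1.53	1.352	87.88	15.1	1.9	1.31	69.05	10	0.80	0.48	-1.24	-2.06
hsa-miR-222*	0.71	0.44	61.54	16.70	1.47	1.23	83.64	13.48	0.48	0.69	-2.056	-1.44
hsa-miR-497	0.61	0.37	60.51	16.68	1.29	1.26	97.74	16.98	0.47	0.58	-2.12	-1.7
hsa-miR-675	1.09	0.77	70.73	17.08	2.66	2.26	84.87	12.03	0.41	0.54	-2.42	-1.84
hsa-miR-106b*	0.572	0.571	99.96	72.356	1.44	1.9	131.84	39.01	0.39	0.48	-2.53	-2.04
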