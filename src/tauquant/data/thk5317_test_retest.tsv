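subject_id	roi_name	test	retest	pct_difference
prodromal_AD_1	frontal_cx	1.20	1.20	-0.47
prodromal_AD_1	temporal_cx	1.16	1.14	-1.81
prodromal_AD_1	parietal_cx	1.06	1.05	-0.93
prodromal_AD_1	occipital_cx	1.08	1.08	0.18
prodromal_AD_1	insular_cx	1.29	1.26	-2.03
prodromal_AD_1	anterior_cingulate	1.24	1.22	-1.16
prodromal_AD_1	posterior_cingulate	1.25	1.25	0.31
prodromal_AD_1	hippocampus	1.32	1.30	-1.26
prodromal_AD_1	putamen	1.67	1.66	-0.26
prodromal_AD_1	caudate_nucleus	1.08	1.08	0.41
prodromal_AD_1	thalamus	1.34	1.35	1.04
prodromal_AD_2	frontal_cx	1.13	1.15	2.29
prodromal_AD_2	temporal_cx	1.11	1.13	1.74
prodromal_AD_2	parietal_cx	1.10	1.09	-0.39
prodromal_AD_2	occipital_cx	1.20	1.16	-2.91
prodromal_AD_2	insular_cx	1.22	1.20	-2.30
prodromal_AD_2	anterior_cingulate	1.23	1.26	2.79
prodromal_AD_2	posterior_cingulate	1.21	1.26	4.21
prodromal_AD_2	hippocampus	1.30	1.37	5.36
prodromal_AD_2	putamen	1.46	1.51	2.93
prodromal_AD_2	caudate_nucleus	0.89	1.05	18.92
prodromal_AD_2	thalamus	1.27	1.34	5.38
prodromal_AD_3	frontal_cx	1.24	1.24	-0.20
prodromal_AD_3	temporal_cx	1.14	1.15	0.71
prodromal_AD_3	parietal_cx	1.06	1.05	-0.59
prodromal_AD_3	occipital_cx	1.17	1.18	0.81
prodromal_AD_3	insular_cx	1.31	1.32	1.17
prodromal_AD_3	anterior_cingulate	1.23	1.28	3.68
prodromal_AD_3	posterior_cingulate	1.23	1.29	4.80
prodromal_AD_3	hippocampus	1.44	1.48	3.02
prodromal_AD_3	putamen	1.63	1.62	-0.70
prodromal_AD_3	caudate_nucleus	1.31	1.39	5.72
prodromal_AD_3	thalamus	1.42	1.48	4.43
prodromal_AD_4	frontal_cx	1.17	1.19	1.98
prodromal_AD_4	temporal_cx	1.08	1.10	1.42
prodromal_AD_4	parietal_cx	1.11	1.11	0.05
prodromal_AD_4	occipital_cx	1.10	1.11	0.27
prodromal_AD_4	insular_cx	1.26	1.29	2.86
prodromal_AD_4	anterior_cingulate	1.25	1.25	0.52
prodromal_AD_4	posterior_cingulate	1.28	1.25	-1.84
prodromal_AD_4	hippocampus	1.33	1.30	-2.65
prodromal_AD_4	putamen	1.59	1.63	2.07
prodromal_AD_4	caudate_nucleus	1.00	0.99	-0.58
prodromal_AD_4	thalamus	1.38	1.38	-0.04
CBD	frontal_cx	1.09	1.08	-1.07
CBD	temporal_cx	1.10	1.06	-3.45
CBD	parietal_cx	1.05	1.01	-3.90
CBD	occipital_cx	1.08	1.03	-3.98
CBD	insular_cx	1.23	1.24	0.36
CBD	anterior_cingulate	1.14	1.11	-2.29
CBD	posterior_cingulate	1.21	1.15	-5.28
CBD	hippocampus	1.19	1.11	-6.75
CBD	putamen	1.79	1.76	-1.58
CBD	caudate_nucleus	0.74	0.74	-0.70
CBD	thalamus	1.20	1.18	-1.81
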