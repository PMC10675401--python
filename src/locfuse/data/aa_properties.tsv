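property	A	R	N	D	C	Q	E	G	H	I	L	K	M	F	P	S	T	W	Y	V
kyte_doolittle_hydropathy	1.8	-4.5	-3.5	-3.5	2.5	-3.5	-3.5	-0.4	-3.2	4.5	3.8	-3.9	1.9	2.8	-1.6	-0.8	-0.7	-0.9	-1.3	4.2
hopp_woods_hydrophilicity	-0.5	3.0	0.2	3.0	-1.0	0.2	3.0	0.0	-0.5	-1.8	-1.8	3.0	-1.3	-2.5	0.0	0.3	-0.4	-3.4	-2.3	-1.5
eisenberg_consensus_hydrophobicity	0.62	-2.53	-0.78	-0.90	0.29	-0.85	-0.74	0.48	-0.40	1.38	1.06	-1.50	0.64	1.19	0.12	-0.18	-0.05	0.81	0.26	1.08
fauchere_pliska_hydrophobicity	0.31	-1.01	-0.60	-0.77	1.54	-0.22	-0.64	0.00	0.13	1.80	1.70	-0.99	1.23	1.79	0.72	-0.04	0.26	2.25	0.96	1.22
janin_buried_transfer	0.3	-1.4	-0.5	-0.6	0.9	-0.7	-0.7	0.3	-0.1	0.7	0.5	-1.8	0.4	0.5	-0.3	-0.1	-0.2	0.3	-0.4	0.6
molecular_weight	89.09	174.20	132.12	133.10	121.16	146.15	147.13	75.07	155.16	131.17	131.17	146.19	149.21	165.19	115.13	105.09	119.12	204.23	181.19	117.15
residue_volume	88.6	173.4	114.1	111.1	108.5	143.8	138.4	60.1	153.2	166.7	166.7	168.6	162.9	189.9	112.7	89.0	116.1	227.8	193.6	140.0
bulkiness	11.50	14.28	12.82	11.68	13.46	14.45	13.57	3.40	13.69	21.40	21.40	15.71	16.25	19.80	17.43	9.47	15.77	21.67	18.03	21.57
polarity_grantham	8.1	10.5	11.6	13.0	5.5	10.5	12.3	9.0	10.4	5.2	4.9	11.3	5.7	5.2	8.0	9.2	8.6	5.4	6.2	5.9
polarity_zimmerman	0.00	52.00	3.38	49.70	1.48	3.53	49.90	0.00	51.60	0.13	0.13	49.50	1.43	0.35	1.58	1.67	1.66	2.10	1.61	0.13
isoelectric_point	6.00	10.76	5.41	2.77	5.07	5.65	3.22	5.97	7.59	6.02	5.98	9.74	5.74	5.48	6.30	5.68	5.60	5.89	5.66	5.96
flexibility_average	0.357	0.529	0.463	0.511	0.346	0.493	0.497	0.544	0.323	0.462	0.365	0.466	0.295	0.314	0.509	0.507	0.444	0.305	0.420	0.386
helix_propensity_chou_fasman	1.42	0.98	0.67	1.01	0.70	1.11	1.51	0.57	1.00	1.08	1.21	1.16	1.45	1.13	0.57	0.77	0.83	1.08	0.69	1.06
sheet_propensity_chou_fasman	0.83	0.93	0.89	0.54	1.19	1.10	0.37	0.75	0.87	1.60	1.30	0.74	1.05	1.38	0.55	0.75	1.19	1.37	1.47	1.70
turn_propensity_chou_fasman	0.66	0.95	1.56	1.46	1.19	0.98	0.74	1.56	0.95	0.47	0.59	1.01	0.60	0.60	1.52	1.43	0.96	0.96	1.14	0.50
accessible_surface_area	115	225	160	150	135	180	190	75	195	175	170	200	185	210	145	115	140	255	230	155
hydration_potential	1.94	-19.92	-9.68	-10.95	-1.24	-9.38	-10.20	2.39	-10.27	2.15	2.28	-9.52	-1.48	-0.76	0.00	-5.06	-4.88	-5.88	-6.11	1.99
refractivity	4.34	26.66	13.28	12.00	35.77	17.56	17.26	0.00	21.81	19.06	18.78	21.29	21.64	29.40	10.93	6.35	11.01	42.53	31.53	13.92
relative_mutability	100	65	134	106	20	93	102	49	66	96	40	56	94	41	56	120	97	18	41	74
net_charge_ph7	0	1	0	-1	0	0	-1	0	0.1	0	0	1	0	0	0	0	0	0	0	0
side_chain_heavy_atoms	1	7	4	4	2	5	5	0	6	4	4	5	4	7	3	2	3	10	8	3
side_chain_pka	0	12.48	0	3.65	8.18	0	4.25	0	6.00	0	0	10.53	0	0	0	0	0	0	10.07	0
tm_insertion_free_energy	0.11	2.58	2.05	3.49	-0.13	2.36	2.68	0.74	2.06	-0.60	-0.55	2.71	-0.10	-0.32	2.23	0.84	0.52	0.30	0.68	-0.31
mean_fractional_area_buried	0.74	0.64	0.63	0.62	0.91	0.62	0.62	0.72	0.78	0.88	0.85	0.52	0.85	0.88	0.64	0.66	0.70	0.85	0.76	0.86
bull_breese_surface_tension	0.61	0.69	0.89	0.61	0.36	0.97	0.51	0.81	0.69	-1.45	-1.65	0.46	-0.66	-1.52	-0.17	0.42	0.29	-1.20	-1.43	-0.75
parker_hydrophilicity	2.1	4.2	7.0	10.0	1.4	6.0	7.8	5.7	2.1	-8.0	-9.2	5.7	-4.2	-9.2	2.1	6.5	5.2	-10.0	-1.9	-3.7
welling_antigenicity	0.115	0.058	-0.077	0.065	-0.120	-0.011	-0.071	-0.184	0.312	-0.292	0.075	0.206	-0.385	-0.141	-0.016	-0.026	-0.045	-0.114	0.013	-0.013
miyazawa_contact_energy	5.33	4.18	3.71	3.59	7.93	3.87	3.65	4.48	5.10	8.83	8.47	2.95	8.95	9.03	3.87	4.09	4.49	7.66	5.89	7.63
guy_transfer_energy	0.10	1.91	0.48	0.78	-1.42	0.95	0.83	0.33	-0.50	-1.13	-1.18	1.40	-1.59	-2.12	0.73	0.52	0.07	-0.51	-0.21	-1.27
roseman_hydrophobicity	0.39	-3.95	-1.91	-3.81	0.25	-1.30	-2.91	0.00	-0.64	1.82	1.82	-2.77	0.96	2.27	0.99	-1.24	-1.00	2.13	1.47	1.30
sweet_eisenberg_om	-0.40	-0.59	-0.92	-1.31	0.17	-0.91	-1.22	-0.67	-0.64	1.25	1.22	-0.67	1.02	1.92	-0.49	-0.55	-0.28	0.50	1.67	0.91
cowan_hplc_retention	0.35	-1.50	-0.44	-0.32	0.76	-0.22	-0.64	0.00	-0.65	1.83	1.80	-2.36	1.10	1.69	0.84	-0.19	-0.27	1.35	0.39	1.32
rao_argos_membrane_propensity	1.36	0.15	0.33	0.11	1.27	0.33	0.25	1.09	0.68	1.44	1.47	0.09	1.42	1.57	0.54	0.97	1.08	1.00	0.83	1.37
surrounding_hydrophobicity	12.97	11.72	11.42	10.85	14.63	11.76	11.89	12.43	12.16	15.67	14.90	11.36	14.39	14.00	11.37	11.23	11.69	13.93	13.42	15.71
zimmerman_hydrophobicity	0.83	0.83	0.09	0.64	1.48	0.00	0.65	0.10	1.10	3.07	2.52	1.60	1.40	2.75	2.70	0.14	0.54	0.31	2.97	1.79
black_mould_hydrophobicity	0.616	0.000	0.236	0.028	0.680	0.251	0.043	0.501	0.165	0.943	0.943	0.283	0.738	1.000	0.711	0.359	0.450	0.878	0.880	0.825
abraham_leo_hydrophobicity	0.44	-2.42	-1.32	-0.31	0.58	-0.71	-0.34	0.00	-0.01	2.46	2.46	-2.45	1.10	2.54	1.29	-0.84	-0.41	2.56	1.63	1.73
levitt_helix_frequency	1.29	0.96	0.90	1.04	1.11	1.27	1.44	0.56	1.22	0.97	1.30	1.23	1.47	1.07	0.52	0.82	0.82	0.99	0.72	0.91
levitt_sheet_frequency	0.90	0.99	0.76	0.72	0.74	0.80	0.75	0.92	1.08	1.45	1.02	0.77	0.97	1.32	0.64	0.95	1.21	1.14	1.25	1.49
levitt_turn_frequency	0.77	0.88	1.28	1.41	0.81	0.98	0.99	1.64	0.68	0.51	0.58	0.96	0.41	0.59	1.91	1.32	1.04	0.76	1.05	0.47
membrane_recognition_factor	78	95	94	81	89	87	78	84	84	88	85	87	80	81	91	107	93	104	84	89
heat_capacity	29.22	26.37	38.30	37.09	50.70	44.02	41.84	23.71	59.64	45.00	48.03	57.10	69.32	48.52	36.13	32.40	35.20	56.92	51.73	40.35
swissprot_composition	8.25	5.53	4.06	5.45	1.37	3.93	6.75	7.07	2.27	5.96	9.66	5.84	2.42	3.86	4.70	6.56	5.34	1.08	2.92	6.87
grantham_composition	0.00	0.65	1.33	1.38	2.75	0.89	0.92	0.74	0.58	0.00	0.00	0.33	0.00	0.00	0.39	1.42	0.71	0.13	0.20	0.00
charton_steric_parameter	0.52	0.68	0.76	0.76	0.62	0.68	0.68	0.00	0.70	1.02	0.98	0.68	0.78	0.70	0.36	0.53	0.50	0.70	0.70	0.76
normalized_vdw_volume	1.00	6.13	2.95	2.78	2.43	3.95	3.78	0.00	4.66	4.00	4.00	4.77	4.43	5.89	2.72	1.60	2.60	8.08	6.47	3.00
chothia_buried_proportion	0.38	0.01	0.12	0.15	0.45	0.07	0.18	0.36	0.17	0.60	0.45	0.03	0.40	0.50	0.18	0.22	0.23	0.27	0.15	0.54
helix_ddg_pace_scholtz	0.00	0.21	0.65	0.69	0.68	0.39	0.40	1.00	0.61	0.41	0.21	0.26	0.24	0.54	3.16	0.50	0.66	0.49	0.53	0.61
beta_branching	0	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	1	0	0	1
side_chain_hbond_donors	0	5	2	0	1	2	0	0	1	0	0	3	0	0	0	1	1	1	1	0
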