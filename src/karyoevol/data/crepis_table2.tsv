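species	infraspecific	accession	lineage	clade	ploidy	two_n	x	formula	ai	one_c_pg	one_c_sd	standard
Crepis aculeata	-	1	crepis_ss	IVb	2	8	4	2n = 2x = 8 = 6sm + 2st	1.38	2.89	0.04	Pisum sativum
Crepis albida	-	1	crepis_ss	IV	2	10	5	2n = 2x = 10 = 4m + 2sm + 4st	7.07	3.08	0.03	Pisum sativum
Crepis albida	-	2	crepis_ss	IV	2	10	5	2n = 2x = 10 = 4m + 2sm + 4st	7.39	-	-	-
Crepis alpestris	-	1	crepis_ss	IVc	2	8	4	2n = 2x = 8 = 4sm + 4st	3.96	2.99	0.03	Pisum sativum
Crepis alpestris	-	2	crepis_ss	IVc	2	8	4	2n = 2x = 8 = 4sm + 4st	2.52	-	-	-
Crepis alpina	-	1	crepis_ss	IVb	2	10	5	2n = 2x = 10 = 2m + 4sm + 4st	13.47	2.20	0.05	Zea mays
Crepis aspera	-	1	crepis_ss	IVb	2	8	4	2n = 2x = 8 = 4sm + 4st	4.24	2.15	0.02	Solanum pseudocapsicum
Crepis aurea	-	1	crepis_ss	IV	2	10	5	2n = 2x = 10 = 4m + 4sm + 2st	5.93	1.63	0.10	Solanum lycopersicum
Crepis biennis	-	2	crepis_ss	III	8	40	5	-	-	10.45	0.33	Pisum sativum
Crepis capillaris	-	1	crepis_ss	IVc	2	6	3	2n = 2x = 6 = 2sm + 4st	20.15	2.07	0.08	Zea mays
Crepis conyzifolia	-	1	crepis_ss	IVa	2	8	4	2n = 2x = 8 = 2sm + 6st	3.74	6.08	0.16	Pisum sativum
Crepis conyzifolia	-	2	crepis_ss	IVa	2	8	4	2n = 2x = 8 = 2sm + 6st	2.06	-	-	-
Crepis conyzifolia	dshimilensis	1	crepis_ss	IVa	2	8	4	2n = 2x = 8 = 2sm + 6st	3.67	-	-	-
Crepis dioscoridis	-	1	crepis_ss	IVa	2	8	4	2n = 2x = 8 = 2sm + 6st	4.74	4.58	0.13	Secale cereale
Crepis foetida	-	1	crepis_ss	IV	2	10	5	2n = 2x = 10 = 4m + 4sm + 2st	11.17	2.03	0.08	Solanum pseudocapsicum
Crepis foetida	rhoaedifolia	1	crepis_ss	IV	2	10	5	2n = 2x = 10 = 4m + 4sm + 2st	10.92	2.17	0.02	Solanum pseudocapsicum
Crepis jacquinii	-	1	crepis_ss	I	2	12	6	2n = 2x = 12 = 12sm	5.93	5.12	0.05	Secale cereale
Crepis kotschyana	-	1	crepis_ss	IVb	2	8	4	2n = 2x = 8 = 4sm + 4st	5.54	2.92	0.08	Pisum sativum
Crepis lacera	-	1	crepis_ss	IVa	2	8	4	2n = 2x = 8 = 2sm + 6st	5.54	7.46	0.10	Pisum sativum
Crepis leontodontoides	-	1	crepis_ss	IV	2	10	5	2n = 2x = 10 = 6m + 4sm	5.37	1.06	0.03	Brachypodium hybridum
Crepis lyrata	-	1	crepis_ss	II	2	12	6	2n = 2x = 12 = 12m	5.72	-	-	-
Crepis mollis	-	1	crepis_ss	II	2	12	6	2n = 2x = 12 = 10m + 2sm	9.57	2.53	0.04	Solanum pseudocapsicum
Crepis nicaeensis	-	1	crepis_ss	III	2	8	4	2n = 2x = 8 = 6sm + 2st	3.74	3.17	0.02	Pisum sativum
Crepis nigrescens	-	1	crepis_ss	III	2	8	4	2n = 2x = 8 = 6sm + 2st	3.45	-	-	-
Crepis oporinoides	-	1	crepis_ss	IVc	2	8	4	2n = 2x = 8 = 2m + 2sm + 4st	16.56	-	-	-
Crepis paludosa	-	1	crepis_ss	I	2	12	6	2n = 2x = 12 = 2m + 8sm + 2st	10.92	4.53	0.19	Secale cereale
Crepis pannonica	-	1	crepis_ss	IVa	2	8	4	2n = 2x = 8 = 2sm + 6st	6.52	7.27	0.06	Pisum sativum
Crepis pannonica	-	2	crepis_ss	IVa	2	8	4	2n = 2x = 8 = 2sm + 6st	6.41	-	-	-
Crepis polymorpha	-	1	crepis_ss	IVc	2	8	4	2n = 2x = 8 = 6sm + 2st	1.61	3.13	0.02	Pisum sativum
Crepis pygmaea	-	1	crepis_ss	II	2	12	6	2n = 2x = 12 = 12m	7.53	-	-	-
Crepis pyrenaica	-	1	crepis_ss	IVc	2	8	4	2n = 2x = 8 = 2m + 2sm + 4st	11.66	3.54	0.05	Secale cereale
Crepis rubra	-	1	crepis_ss	IVb	2	10	5	2n = 2x = 10 = 4m + 6st	12.85	2.86	0.07	Pisum sativum
Crepis setosa	-	1	crepis_ss	IVb	2	8	4	2n = 2x = 8 = 6sm + 2st	10.66	1.67	0.02	Solanum lycopersicum
Crepis setosa	-	2	crepis_ss	IVb	2	8	4	2n = 2x = 8 = 6sm + 2st	7.30	-	-	-
Crepis sibirica	-	1	crepis_ss	IVb	2	10	5	2n = 2x = 10 = 2m + 4sm + 4st	14.44	6.98	0.04	Pisum sativum
Crepis succisifolia	-	1	crepis_ss	II	2	12	6	2n = 2x = 12 = 10m + 2sm	10.77	2.34	0.05	Solanum pseudocapsicum
Crepis syriaca	-	1	crepis_ss	IVb	2	10	5	2n = 2x = 10 = 4m + 6st	75.39	2.39	0.28	Solanum pseudocapsicum
Crepis taraxacifolia	-	1	crepis_ss	IVc	2	8	4	2n = 2x = 8 = 6sm + 2st	1.01	2.47	0.58	Pisum sativum
Crepis tectorum	-	1	crepis_ss	III	2	8	4	2n = 2x = 8 = 6sm + 2st	2.308	3.06	0.05	Pisum sativum
Crepis vesicaria	-	3	crepis_ss	IVc	2	8	4	2n = 2x = 8 = 6sm + 2st	2.38	2.43	0.03	Solanum pseudocapsicum
Crepis vesicaria	-	1	crepis_ss	IVc	4	16	4	2n = 4x = 16 = 12sm + 4st	2.68	2.78	0.09	Pisum sativum
Crepis vesicaria	-	2	crepis_ss	IVc	4	16	4	2n = 4x = 16 = 12sm + 4st	3.05	-	-	-
Crepis zacintha	-	1	crepis_ss	IVb	2	6	3	2n = 2x = 6 = 2m + 4sm	18.61	1.03	0.02	Brachypodium hybridum
Crepis magellensis	-	1	lagoseris	Lagoseris	2	10	5	2n = 2x = 10 = 2m + 4sm + 4st	5.26	-	-	-
Crepis palaestina	-	1	lagoseris	Lagoseris	2	8	4	2n = 2x = 8 = 2m + 2sm + 4st	10.45	7.05	0.19	Pisum sativum
Crepis praemorsa	-	1	lagoseris	Lagoseris	2	8	4	2n = 2x = 8 = 2m + 2sm + 4st	27.15	-	-	-
Crepis pulchra	-	1	lagoseris	Lagoseris	2	8	4	2n = 2x = 8 = 2m + 2sm + 4st	10.2	5.59	0.12	Pisum sativum
Crepis sancta	-	1	lagoseris	Lagoseris	2	10	5	2n = 2x = 10 = 2m + 4sm + 4st	5.37	1.60	0.02	Zea mays
Lapsana communis	-	1	lagoseris	Lagoseris	2	14	7	2n = 2x = 14 = 12m + 2sm	12.06	1.22	0.04	Zea mays
Lapsana communis	-	2	lagoseris	Lagoseris	2	14	7	2n = 2x = 14 = 12m + 2sm	12.70	-	-	-
Lapsana communis	-	3	lagoseris	Lagoseris	2	14	7	2n = 2x = 14 = 12m + 2sm	13.67	-	-	-
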