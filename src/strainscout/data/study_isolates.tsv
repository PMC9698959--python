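extract_id	strain_id	phylum	genus	closest_relative	similarity_pct	is_blank
01	HEG41_91	Proteobacteria	Bradyrhizobium	Bradyrhizobium uaiense UFLA03 164 KC879705	97.02	0
02	4RS2_G4	Proteobacteria	Sulfitobacter	Sulfitobacter dubius DQ915635	99.67	0
03	JAB_HD_127b	Actinobacteria	Rhodococcus	Rhodococcus qingshengii JCM 15477 DQ090961	100.00	0
04	PCS2D_E11	Proteobacteria	Oceanisphaera	Oceanisphaera psychrotolerans KF418814	99.89	0
05	JAB_HD_128b	Proteobacteria	Devosia	Devosia psychrophila GU441678	98.83	0
06	JAB_HD_2a	Actinobacteria	Rhodococcus	Rhodococcus qingshengii JCM 15477 DQ090961	100.00	0
07	JAB_HD_137a	Actinobacteria	Rhodococcus	Rhodococcus jostii KF410370	99.24	0
08	JAB_HD_121a	Actinobacteria	Microbacterium	Microbacterium marinum EF204420	100.00	0
09	4RS2_G3b	Proteobacteria	Aliidiomarina	Aliidiomarina soli KX548074	97.10	0
10	4RW5_PS1	Proteobacteria	Alteromonas	Alteromonas macleodii AB681740	99.35	0
11	CS1_PP3	Proteobacteria	Pseudoalteromonas	Pseudoalteromonas shioyasakiensis AB720724	99.65	0
12	4CH2_twe	Proteobacteria	Vibrio	Vibrio kanaloae CAIM 485 MT757984	99.85	0
13	JAB_HD_4a2	Actinobacteria	Aeromicrobium	Aeromicrobium ginsengisoli AB245394	99.47	0
14	4RS2_G3a	Proteobacteria	Halomonas	Halomonas alkaliphila AJ640133	99.93	0
15	4RW5_PS3	Proteobacteria	Pseudovibrio	Pseudovibrio ascidiaceicola AB681198	98.51	0
16	3RW5_S4aa	Bacteroidetes	Maribacter	Maribacter litoralis MG456900	99.93	0
17	JAB_HD_102a2	Proteobacteria	Pseudomonas	Pseudomonas pelagia CL-AP6 EU888911	98.79	0
18	4d1_twe	Proteobacteria	Pseudomonas	Pseudomonas knackmussii B13 AJ272544	99.67	0
19	4RS2_G7	Proteobacteria	Lutimaribacter	Lutimaribacter pacificus DQ659449	97.04	0
20	JAB_HD_109a	Proteobacteria	Pseudorhodobacter	Pseudorhodobacter ponti KX771233	97.15	0
21	RW5_G2	Bacteroidetes	Altibacter-Rhodococcus	Rhodococcus yunnanensis AY602219	99.33	0
22	CS1PS2a	Proteobacteria	Paracoccus	Paracoccus indicus MG845150	99.77	0
23	D100_Iso2	Proteobacteria	Aquicoccus	Aquicoccus porphyridii MF113254	96.82	0
24	MEBiC05055	Proteobacteria	Tateyamaria	Tateyamaria armeniaca LC464518	98.34	0
25	DSM_16472T	Proteobacteria	Sulfitobacter	Sulfitobacter dubius DQ915635	100.00	0
26	DSM_10251T	Proteobacteria	Marinovum	Marinovum algicola DG898 DSM 27768	100.00	0
27	DSM_27768	Proteobacteria	Marinovum	Marinovum algicola FF3 DSM 10251T	100.00	0
29	C05C_116	Proteobacteria	Sulfitobacter	Sulfitobacter pseudonitzschiae KF006321	99.50	0
30	A11D_105	Proteobacteria	Sulfitobacter	Sulfitobacter porphyrae AB758574	99.85	0
31	A05D_005	Proteobacteria	Aquicoccus	Aquicoccus porphyridii MF113254	100.00	0
32	C05C_110	Proteobacteria	Hoeflea	Hoeflea alexandrii MT760263	99.69	0
33	H01Y_008A	Proteobacteria	Fretibacter	Fretibacter rubidus FJ394547	97.12	0
34	RW5_G4	Proteobacteria	Amylibacter	Amylibacter cionae KX790330	99.19	0
35	JAB_HD_121b	Proteobacteria	Pseudorhodobacter	Pseudorhodobacter wandonensis JN247434	99.18	0
36	JAB_HD_38	Bacteroidetes	Algoriphagus	Algoriphagus aquaemixtae KY661386	99.26	0
112	M64	Bacteroidetes	Flavobacterium	Flavobacterium circumlabens P5626 MH100898	98.80	0
122	M66	Bacteroidetes	Flavobacterium	Flavobacterium terriphilum CUG00004 KT592306	99.12	0
132	M20	Actinobacteria	Rubrobacter	Rubrobacter radiotolerans X87134	93.95	0
212	M55	Proteobacteria	Altererythrobacter	Altererythrobacter epoxidivorans DQ304436	97.94	0
222	M62	Firmicutes	Bacillus	Bacillus mobilis MCCC 1A05942 KJ812449	99.93	0
232	M09	Proteobacteria	Altererythrobacter	Altererythrobacter aquiaggeris KX812543	98.73	0
312	SEG27_38	Bacteroidetes	Chitinophaga	Chitinophaga flava MH553387	93.57	0
322	AEG42_45	Actinobacteria	Sporichthya	Sporichthya brevicatena AB006164	96.46	0
332	AEG42_13	Actinobacteria	Nocardioides	Nocardioides humi EF623863	96.86	0
342	ACS3D_E6	Bacteroidetes	Ulvibacter	Ulvibacter antarcticus AB681898	97.28	0
352	HEG41_64b	Bacteroidetes	Niastella	Niastella populi EU877262	96.17	0
362	SEG27_44	Bacteroidetes	Pseudoflavitalea	Pseudoflavitalea rhizosphaerae KU379667	94.04	0
372	AEG42_46	Bacteroidetes	Flavitalea	Flavitalea flava KX762320	99.80	0
382	SEG27_28	Bacteroidetes	Niveitalea	Niveitalea solisilvae KX268597	92.80	0
392	AEG42_23	Bacteroidetes	Ferruginibacter	Ferruginibacter yonginensis MT760289	93.85	0
412	PCS2D_E7	Proteobacteria	Marinomonas	Marinomonas atlantica LN909522	99.86	0
422	CS3_PS3b	Proteobacteria	Amylibacter	Amylibacter lutimaris MF113253	99.85	0
432	3RW5_PP6	Bacteroidetes	Ulvibacter	Ulvibacter antarcticus AB681898	96.77	0
442	ACS3C_E5	Proteobacteria	Pseudoalteromonas	Pseudoalteromonas shioyasakiensis SE3 AB720724	99.65	0
452	2CW3_G4	Bacteroidetes	Balneola	Balneola vulgaris AY576749	94.85	0
462	M68	Bacteroidetes	Arenibacter	Arenibacter algicola FJ176555	99.91	0
472	RS2_PS_4	Proteobacteria	Pararhodobacter	Pararhodobacter oceanensis KY009733	99.85	0
482	M72	Bacteroidetes	Algoriphagus	Algoriphagus jejuensis EF217418	98.79	0
2F2	ARW1_2F2	Proteobacteria	Arcobacter	Arcobacter lekithochrous LT629298	98.16	0
2G2	ARW1_2G2	Proteobacteria	Arcobacter	Arcobacter lekithochrous LT629298	98.17	0
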