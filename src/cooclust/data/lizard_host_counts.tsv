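Host	Proteobacteria	Firmicutes	Bacteroidetes	Actinobacteria	Basidiobolales	Mucorales	Tritrichomonadida	Eugregarinorida	Orthoptera	Diptera	Hemiptera	Coleoptera	Hymenoptera	Psocoptera	Araneae	Non-target
Anolis 1	12732	10934	2777	164	259	57	31	3	13	6	1	1	1	0	0	2112
Anolis 2	1592	10507	13389	168	633	2	354	5	1	0	0	0	0	0	0	3223
Anolis 3	7645	9962	14143	70	276	2	0	0	18	2	0	0	0	475	0	553
Anolis 4	11550	10752	2966	621	2098	6	0	7	0	1108	0	0	15	0	0	713
Anolis 5	7086	7713	9320	18	1446	479	10	0	0	0	0	0	450	0	0	209
Anolis 6	10190	2970	15	594	0	577	0	0	0	1	0	0	0	0	1	603
Anolis 7	3736	3714	5045	121	993	176	236	38	2	1	2	0	0	3	0	38
Anolis 8	4332	2607	6134	4	723	8	0	1	0	0	0	0	0	0	6	486
Anolis 9	11905	3826	9802	165	84	9	0	1	0	0	46	0	0	0	0	1639
Anolis 10	11523	2961	12882	430	8	0	0	16	3	0	0	13	1	0	1	1525
Anolis 11	2812	5471	6578	116	54	5	1	5	0	0	0	0	14	0	0	1215
Anolis 12	105187	56219	6954	141	331	2100	3	0	9	0	0	0	0	0	0	16069
Anolis 13	7459	3175	7338	4	768	1218	0	0	0	2860	0	0	0	0	0	119
Anolis 14	7296	12421	14393	402	1454	65	1582	0	0	0	0	0	4	0	0	4248
Anolis 15	6244	9269	10347	68	153	1	0	4	6	1	0	1	1	0	0	2136
Anolis 16	6195	4686	7541	137	247	886	78	0	1	2	0	0	0	0	0	345
Anolis 17	2871	3530	6324	113	709	1291	330	0	0	0	0	0	3	0	0	190
Anolis 18	22923	2814	2543	36	4	1	0	7	1	1	0	1	0	0	55	2006
Holcosus 1	7960	1571	11258	68	777	0	0	5	0	0	0	1661	0	0	0	1201
Holcosus 2	31963	3398	9788	80	853	417	0	5	1	0	1	2747	19	0	1	2031
Holcosus 3	12542	10786	3849	47	3	24	0	1	2	0	0	0	0	2313	0	1517
Holcosus 4	3021	10128	14511	46	0	0	0	2	0	0	4	0	0	0	0	393
Holcosus 5	7433	3637	4077	8	1016	249	0	0	11	1	0	0	0	0	1	245
Holcosus 6	5994	4999	5202	26	3	1288	0	2	1	0	0	2	1	0	0	1469
Holcosus 7	9777	14347	550	32	318	5	0	1	1	0	0	0	0	0	0	1715
Holcosus 8	33691	4018	733	226	225	6	2	10	8	0	0	0	6	0	0	4088
Holcosus 9	6200	9018	86	82	1	11	2	0	3024	0	0	0	0	0	21	3751
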