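# Published group-level decay and abundance summaries for pelagic communities
# sampled during the Malaspina 2010 circumnavigation (tropical/subtropical
# Atlantic, Indian and Pacific Oceans). One row per biological group:
# logarithmic time-decay slope c (similarity per ln day), initial similarity
# S0 (mean Jaccard similarity over station pairs with surface-ocean transit
# time <= 100 days), community halving-time HT (years), body-size range and
# mean (mm), sampling depth (m), habitat (E epipelagic, N neustonic,
# M mesopelagic), and mean local abundance (individuals per cubic metre;
# reported for the nine main groups only). main_group = 1 marks the nine
# main biological groups; all_groups = 1 marks membership in the 16-group
# set ("microbial eukaryotes all" aggregates eight of its subgroups and is
# excluded there). Gelatinous zooplankton size mean is taken as 5 mm (the
# source prints the range ">5" with no mean). version: 1
group	slope_c	s0	halving_time_years	size_range_mm	size_mean_mm	depth_m	habitat	main_group	all_groups	abundance_per_m3
Prokaryotes	-0.0232	0.52	5094	0.0003-0.001	0.0005	0	E	1	1	3.30e11
Small heterotrophic flagellates	-0.0231	0.34	56	0.0008-0.003	0.002	0	E	0	1
Green algae	-0.0222	0.24	5	0.0008-0.003	0.0025	0	E	0	1
Fungi	-0.0194	0.16	3	0.0008-0.003	0.003	0	E	0	1
Microbial eukaryotes all	-0.0102	0.22	866	0.0008-0.003	0.002	0	E	1	0	1.72e9
Parasites	-0.0100	0.22	802	0.0008-0.003	0.004	0	E	0	1
Cercozoa	-0.0121	0.12	12.5	0.0008-0.003	0.005	0	E	0	1
Large flagellates	-0.0181	0.39	1215	0.0008-0.003	0.006	0	E	0	1
Coccolithophores 0-160 m	-0.0341	0.52	198	0.002-0.5	0.014	0-160	E	1	1	8.08e6
Diatoms 0-160 m	-0.0275	0.27	158	0.002-0.4	0.033	0-160	E	1	1	7.16e6
Diatoms surface	-0.0206	0.17	1	0.002-0.4	0.033	0	E	0	1
Dinoflagellates 0-160 m	-0.0156	0.35	7325	0.002-0.5	0.043	0-160	E	1	1	2.80e6
Dinoflagellates surface	-0.0046	0.19	14931726	0.002-0.5	0.043	0	E	0	1
Mesozooplankton 0-200 m	-0.0135	0.16	18	0.3-5	2.65	0-200	E	1	1	6.00e3
Gelatinous zooplankton	-0.0336	0.38	15.5	>5	5	0	N	1	1	0.04235
Macrozooplankton	-0.0657	0.55	2	4-15	5.4	0	N	1	1	0.179
Myctophids	-0.0807	0.47	1	20-110	35	0	M&N	1	1	0.0035
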