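#rna_id	position	base	guides	noncanonical
18S	28	A	U27	0
18S	38	C	SnoR66	0
18S	123	U	SnoR116	0
18S	162	A	SnoR18	0
18S	213	U	SnoR65;SnoR146	0
18S	246	G	SnoR124	0
18S	392	G	SnoR30	0
18S	418	C	U14	0
18S	440	A	SnoR15;U16	0
18S	468	A	SnoR17	0
18S	473	C	SnoR7	0
18S	545	A	SnoR41Y	0
18S	582	U	SnoR77Y	0
18S	599	G	U54	0
18S	604	U	SnoR115	0
18S	615	U	SnoR13	0
18S	623	A	U36	0
18S	780	A	SnoR119	0
18S	796	A	SnoR25	0
18S	801	A	SnoR53Y	0
18S	978	A	SnoR59	0
18S	1013	U	SnoR20.1	0
18S	1219	C	SnoR166	0
18S	1235	U	SnoR14	0
18S	1264	U	SnoR8;SnoR67	0
18S	1266	U	SnoR32	0
18S	1273	U	U33;SnoR34	0
18S	1275	G	SnoR21	0
18S	1330	A	SnoR32	0
18S	1384	U	U61.1	0
18S	1434	G	SnoR19	0
18S	1448	U	SnoR19	0
18S	1579	A	SnoR8	0
18S	1645	C	U43	0
18S	1758	A	SnoR23	0
25S	44	U	SnoR120	0
25S	48	U	SnoR16	0
25S	144	U	SnoR36	0
25S	399	G	SnoR65	0
25S	661	A	U18	0
25S	675	C	SnoR58Y	0
25S	676	U	SnoR58Y	1
25S	803	U	SnoR14	0
25S	814	G	SnoR39BY	0
25S	816	A	U51	0
25S	826	A	U80	0
25S	885	A	SnoR72Y	0
25S	917	G	U80	0
25S	945	A	SnoR12	0
25S	1067	U	SnoR41Y	0
25S	1143	A	U38	0
25S	1263	A	SnoR22	0
25S	1278	U	SnoR22	0
25S	1377	A	SnoR7	0
25S	1447	C	U24	0
25S	1459	A	U24	0
25S	1460	G	U24	1
25S	1479	C	SnoR147	0
25S	1518	C	U49;SnoR121	0
25S	1847	C	SnoR128;SnoR129	0
25S	1850	C	SnoR149	0
25S	1855	G	SnoR59	0
25S	1860	C	SnoR15;U55	0
25S	1892	U	U34	0
25S	2114	U	SnoR117	0
25S	2125	G	U60	0
25S	2127	A	SnoR12	0
25S	2198	C	SnoR118	0
25S	2215	A	U37	0
25S	2221	A	U36	0
25S	2237	G	U36	0
25S	2257	A	U40	0
25S	2282	A	U15	0
25S	2289	G	U15	0
25S	2294	C	SnoR131;SnoR132;SnoR133	0
25S	2322	A	U30	0
25S	2327	A	SnoR44	0
25S	2338	C	SnoR44	0
25S	2362	A	SnoR43.12	0
25S	2366	C	SnoR37	0
25S	2392	G	SnoR29	0
25S	2396	G	SnoR28	0
25S	2410	G	SnoR29	0
25S	2411	U	SnoR29	1
25S	2422	U	SnoR37	0
25S	2456	U	SnoR16.1	0
25S	2494	U	SnoR123	0
25S	2620	G	SnoR35;U31	0
25S	2641	A	SnoR27;SnoR68Y	0
25S	2651	U	SnoR10	0
25S	2652	G	SnoR10	1
25S	2683	C	SnoR148	0
25S	2736	U	SnoR68	0
25S	2792	G	SnoR1	0
25S	2794	G	SnoR1	1
25S	2816	G	SnoR38Y	0
25S	2837	C	SnoR24	0
25S	2880	C	U49	0
25S	2884	U	SnoR64	0
25S	2912	A	SnoR31	0
25S	2918	G	SnoR34;SnoR6.3	0
25S	2922	U		0
25S	2923	G		0
25S	2935	A	SnoR18	0
25S	2947	A	U29	0
25S	2949	C	SnoR69Y	0
25S	2960	C	U35	0
25S	3292	G	U33	0
25S	3301	U	SnoR13	0
5.8S	47	A	SnoR9	0
5.8S	79	G	SnoR39BY	0
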