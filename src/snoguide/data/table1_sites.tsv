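subunit	dd_site	dd_guides	register_note	sc_site	sc_guide	hs_site	hs_guide	at_site	at_guide
SSU	Am28	CD18		Am28	snR74	Am27	U27	Am28	AtU27
SSU	Cm38	CD35
SSU	Am432	CD8		Am436	snR87	Am484	U16	Am438	AtU16
SSU	Am466	CD8
SSU	Um571	CD21		Um578	snR77	Um627	HBII-135	Um580	AtsnoR77Y
SSU	Am612	CD25		Am619	snR47	Am668	U36A/B	Am621	AtU36
SSU	Am796	CD19
SSU	Cm991	CD7
SSU	Am1133	CD10
SSU	Um1255	CD20
SSU	Um1264	CD29		Um1269	snR55	Um1326	U33	Um1270	AtsnoR34
SSU	Gm1266	CD37		Gm1271	snR40	Gm1328	U232A	Gm1272	AtsnoR21
SSU	Um1456	CD1				Um1442	U61	Um1281	AtU61
SSU	Am1469
SSU	Gm1506	CD1		Gm1428	snR56	Gm1490	U25	Gm1431	AtsnoR19
SSU	Gm1589	CD16	+6
SSU	Cm1715	CD28		Cm1639	snR70	Cm1703	U43	Cm1641	AtU43
LSU	Gm711	CD7
LSU	Am841	CD12
LSU	Am844	CD24		Am649	U18	Am1313	U18A/B/C	Am647	AtU18
LSU	Am1370	CD9/13		Am1133	snR61	Am1858	U38A/B	Am1140	AtU38
LSU	Am1463	CD9/13
LSU	Cm1673	CD19		Cm1437	Um24	Cm2338	U24	Cm1439	AtU24
LSU	Am1685	CD19		Am1449	Um24	Am2350	U76	Am1451	AtU24
LSU	Gm1686	CD16		Gm1450	Um24	Gm2351	U24	Gm1452
LSU	Am1689	CD33
LSU	Gm2132	CD1
LSU	Am2159	CD27
LSU	Um2164	CD31
LSU	Um2170	CD17/32		Um1888	snR62	Um2824	U34	Um1882	AtU34
LSU	Am2522	CD4		Am2256	snR63	Am3739	U46
LSU	Am2547			Am2281	snR13	Am3764	U15A/B	Am2271	AtU15
LSU	Gm2554	CD14		Gm2288	snR75			Gm2278	AtU15
LSU	Um2580	CD12/34
LSU	Am2592	CD34
LSU	Cm2603	CD26		Cm2337	snR64	Cm3820	U74
LSU	Gm2661	CD2/3
LSU	Um2683	CD30		Um2417	snR66
LSU	Um2687	CD22		Um2421	snR78	Um3904	U52	Um2411	AtsnoR37
LSU	Gm2952	CD13		Gm2619	snR67	Gm4166	U31	Gm2610	AtsnoR35
LSU	Gm2984	CD5
LSU	Gm3124	CD36
LSU	Gm3148	CD6		Gm2815	snR38	Gm4362	snR38A/B/C	Gm2805	AtsnoR38Y
LSU	Cm3212	CD38
LSU	Um3254	CD25		Um2921	snR52	Um4468
LSU	Gm3255			Gm2922	Spb1	Gm4469
LSU	Am3279	CD11		Am2946	snR71	Am4493	U29	Am2936	AtU29
LSU	Cm3281	CD15		Cm2948	snR69
LSU	Cm3292	CD23		Cm2959	snR73	Cm4506	U35A/B	Cm2949	AtU35
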