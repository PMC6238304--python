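# Published CYP2D6 marker frequencies by population. Marker columns named after a
# defining substitution or structural event hold the corresponding star-allele
# frequency (C100T->*10, G1846A->*4, C2850T->*2, deletion->*5, exon9_conversion->*36);
# plain columns (C1039T, G1661C, G4180C) hold substitution frequencies. ND = not determined.
population	group	region	year	n	method	C100T	C1039T	G1661C	G1846A	C2850T	G4180C	exon9_conversion	deletion	duplication
Karen (current study)	Asian	Southeast Asia	2017	70	DSP/ASO	0.40	0.43	0.76	0.02	0.33	0.76	0.01	0.03	0.01
Thai 2011	Asian	Southeast Asia	2011	286	M/DHPLC	0.45	ND	ND	0.01	0.10	ND	0.16	0.04	0.004
Thai 2012	Asian	Southeast Asia	2012	48	AmpliChip	0.44	ND	ND	0.01	0.10	ND	0.01	0.04	ND
Thai 2013a	Asian	Southeast Asia	2013	114	AmpliChip	0.46	ND	ND	0.01	0.10	ND	0.01	0.04	ND
Thai 2013b	Asian	Southeast Asia	2013	233	AmpliChip	0.48	ND	ND	0.01	0.09	ND	0.01	0.05	0.004
Thai 2016	Asian	Southeast Asia	2016	84	Luminex xTag	0.52	ND	ND	0.01	0.06	ND	ND	ND	0.06
Chinese 2002	Asian	East Asia	2002	223	ASA	0.51	ND	ND	0.002	ND	ND	ND	0.07	0.01
Chinese 2008	Asian	East Asia	2008	400	Sequencing	0.53	ND	ND	0.001	0.11	ND	ND	0.05	0.02
Hong Kong Chinese 2000	Asian	East Asia	2000	119	PCR-RFLP	0.65	ND	ND	0.00	0.08	ND	ND	0.05	ND
Vietnamese 2010	Asian	Southeast Asia	2010	122	mSBE	0.57	ND	ND	ND	0.08	ND	ND	0.06	0.00
Japanese 1999	Asian	East Asia	1999	98	PCR	0.41	ND	ND	0.02	0.09	ND	ND	0.06	ND
Japanese 2000	Asian	East Asia	2000	412	PCR-RFLP	0.38	ND	ND	0.002	0.13	ND	ND	0.05	0.01
Japanese 2003	Asian	East Asia	2003	162	ASA-RFLP	0.38	ND	ND	0.00	0.13	ND	0.01	0.06	ND
Korean 2006	Asian	East Asia	2006	400	Sequencing	0.45	ND	ND	0.003	0.10	ND	ND	0.06	0.01
Korean 2009	Asian	East Asia	2009	758	Sequencing	0.46	ND	ND	ND	0.10	ND	ND	0.06	0.01
Korean 2011	Asian	East Asia	2011	766	SNaPshot	0.43	ND	ND	0.001	0.12	ND	ND	0.06	0.01
South India 2006	Asian	South Asia	2006	447	PCR-RFLP	0.10	ND	ND	0.07	0.35	ND	ND	0.02	ND
Germany 1997	Caucasian	Europe	1997	589	PCR-RFLP	0.02	ND	ND	0.21	0.32	ND	ND	0.02	0.007
Mexican-American 2001	Caucasian	America	2001	349	PCR-RFLP	0.07	ND	ND	0.10	0.23	ND	ND	0.02	0.01
Spanish 2006	Caucasian	Europe	2006	105	RT-PCR	0.02	ND	ND	0.14	0.40	ND	ND	0.03	0.04
African-American 2001	African	America	2001	154	PCR-RFLP	0.08	ND	ND	0.08	0.27	ND	ND	0.06	0.02
African-American 2006	African	America	2006	222	AmpliChip	0.04	ND	ND	0.07	0.05	ND	0.005	0.06	0.05
African-American 2013	African	America	2013	75	mPCR	0.03	ND	ND	0.08	0.29	ND	ND	0.09	ND
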