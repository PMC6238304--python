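# Primer and probe panel with published reference metrics (length, GC%, Tm, amplicon size).
# Probe GC% is printed at integer precision in the source table; probe Tm reflects
# dual-labelled probe chemistry and is not comparable to plain-DNA nearest-neighbor values.
analysis	name	role	sequence	length_bp	gc_percent	tm_c	amplicon_bp
XL-PCR	DPKup	outer	GTTATCCCAGAAGGCTTTGCAGGCTTCA	28	50.0	67.8	5100
XL-PCR	DPKlow	outer	GCCGACTGAGCCCTGGGAGGTAGGTA	26	65.4	71.1	5100
XL-PCR	2D6dupl-F	outer	CCTGGGAAGGCCCCATGGAAG	21	66.7	65.5	3500
XL-PCR	2D6dupl-R	outer	CAGTTACGGCAGTGGTCAGCT	21	57.1	63.2	3500
XL-PCR	5'2D6*5	outer	CACCAGGCACCTGTACTCCTC	21	61.9	62.7	3500
XL-PCR	3'2D6*5	outer	CAGGCATGAGCTAAGGCACCCAGAC	25	60.0	67.9	3500
Int2	5'2D6Int2	nested	TTTTGCACTGTGGGTCCTC	19	52.6	58.5	1101
Int2	3'2D6Int2	nested	CAAGGTGGACACGGAGAAG	19	57.9	58.4	1101
DSP	5'2D6Ex1	nested	GCACAGTCAACACAGCAGGT	20	55.0	61.7	503
DSP	3'2D6Ex1	nested	AATGCCCTTCTCCAGGAAGT	20	50.0	59.2	503
DSP	5'2D6Ex2	nested	TTCCTCCATCACAGAAGGTG	20	50.0	57.4	501
DSP	3'2D6Ex2	nested	CTCCCTAGTGCAGGTGGTTT	20	55.0	59.9	501
DSP	5'2D6Ex34	nested	GTCTTCCCTGAGTGCAAAGG	20	55.0	59.1	754
DSP	3'2D6Ex34	nested	AGTGGGGTCTCCTGGAATG	19	57.9	58.9	754
DSP	5'2D6Ex56	nested	GAGGGACTTGGTGAGGTCAG	20	60.0	60.0	794
DSP	3'2D6Ex56	nested	GACACTCCTTCTTGCCTCCT	20	55.0	59.6	794
DSP	5'2D6Ex7	nested	ATGAACTTTGCTGGGACACC	20	50.0	59.0	505
DSP	3'2D6Ex7	nested	CCAGCCCTGCCTATACTCTG	20	60.0	59.9	505
DSP	5'2D6Ex89	nested	TCTAGTGGGGAGACAAACCAG	21	52.4	59.3	802
DSP	3'2D6Ex89	nested	CTGAGGAGGATGATCCCAAC	20	55.0	57.7	802
ASO	5'2D6C100T	nested	CCTGGTGGACCTGATGCA	18	61.1	59.5	73
ASO	3'2D6C100T	nested	CCCGGGCAGTGGCA	14	78.6	58.7	73
ASO	2D6C100T_WT	probe_wt	CCTGGTGGGTAGCGTG	16	69.0	51.1
ASO	2D6C100T_MT	probe_mut	CCTGGTGAGTAGCGTG	16	63.0	48.5
ASO	5'2D6G1846A	nested	GACCCCTTACCCGCATCTC	19	63.2	60.1	73
ASO	3'2D6G1846A	nested	GCTCACGGCTTTGTCCAAGA	20	55.0	61.5	73
ASO	2D6G1846A_WT	probe_wt	CCCCCAGGACGCC	13	85.0	48.0
ASO	2D6G1846A_MT	probe_mut	CCCCCAAGACGCC	13	77.0	46.0
ASO	5'2D6C2850T	nested	CCTGAGAGCAGCTTCAATGATGA	23	47.8	61.3	67
ASO	3'2D6C2850T	nested	CCATCCCGGCAGAGAACAG	19	63.2	60.7	67
ASO	2D6C2850T_WT	probe_wt	ACTATGCGCAGGTTC	15	53.0	41.9
ASO	2D6C2850T_MT	probe_mut	CACTATGCACAGGTTC	16	50.0	43.4
ASO	5'2D6G4180C	nested	CCACCATGGTGTCTTTGCTTTC	22	50.0	60.9	67
ASO	3'2D6G4180C	nested	GCACAGCACAAAGCTCATAGG	21	52.4	60.4	67
ASO	2D6G4180C_WT	probe_wt	CTGGTGAGCCCATCC	15	67.0	47.4
ASO	2D6G4180C_MT	probe_mut	CTGGTGACCCCATCC	15	67.0	47.4
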