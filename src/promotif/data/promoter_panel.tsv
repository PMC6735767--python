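gene	sequence
ALPL	actcgggccccgcggccgcctttataaggcggcgggggtggtggcccggGCCGCGTTGCG
LIN37	taataggaacaagctactgccgaaggggcccgcccacagaagggtggtgGCCACGGTCCA
DUSP21	agatgggagtggtgagaggagacagaaagagggtggtggccgatagctgGTCCTCTTTCT
MSL1	gcggccagcgagggcagatggaagagTATGAGGAAGAGCCCTCTCGGGGGTGGTGGCGGC
SLC26A1	cagagtccagggcacagaccactgcctgcaggttggcgccaccacccccACTCTCCCCGC
TPRG1L	ccgcggggcggggccgggggcgcggccgggtggtggcggtggctgcggcgacggcggtcG
TYROBP	ccctgtctcctcctcccttctgccaccacccgcctcagacttcctccttCACTTGCCTGG
RRAGA	gagatcgccgccggaagtgggtggtggcggggacgcagcggctccctccCGGAAAGCGAG
CIZ1	ggcaaaatggcgaaatccctctctacaaaaaatacaaacattagccagggtggtggcggg
CNOT2	agggagggagggggtgtgtatgggggtggtggtggACCGGACGTAAAGCGTCGCTGTACT
RPH3A	aggagggagagggggtggtggaggagggagagagggtgggagaaggagtgatgaagatgg
CHD3	ggggaggcgggcgggcggtgggtgggggggtggtgggggggccAGAGCCACAGGATGGCT
USP16	GGGAGGTGGGGGTGGGGTGGTGGTGGCCTAGCCACTTCCCATAATGCCGCGTTCCGGAAG
RAD17	CGAATATTTGAGCTTAGTATTCCCTGTTCACTGTGTGGGGTGGTGGTGGGTCGGCTAGGA
CCR3	aggtggtggcctgcccctccccgcaggcactctgtcccagggagaaatcagaactcttta
GBA2	CACGGCCACTTCTGCATCCAGGTGGGGATGCTGGCACTGAAGGTGGTGGCCCTTCTGGGA
CERCAM	GGAGCCGGGGAAGCCCGGGAGGTGGTGGCCGAGTGGGCGCCGCCCCTCTGGGTCTGCGGC
PYGO2	ttgctccccctccccgcagcgctcagtggtggtggccgcgacgagttccGGTTCCGGTTG
CEP63	GCCTCGCAGGCCACCACCATCCGCACCGTACGACAGGCCGTCCCTCAGCTGCGGCTTCCT
LCN15	caggtggtggcctgggctataaagctggccccctggggcttggggactcAGCACCAGGGG
MTERFD3	ggaagcaaatgcagctggtgcaggagagggaaatgggaattagggtggtGGCAGAGCCCA
ACTR8	cccctggtggggggAGTGCGGAAGCGGTCGTTCTTTTCCGGGTGGTGGCGCGCCGGGACG
SCRN1	tcccactcctctccacctccactgccaccaccctgcaccaagccaccaccatctccagcc
EML3	CTCGGGGTGGTGGTACGGCGCCCTTCGCGCGCGCCCCGGGGTGCTTCCCCTTCCCCTCTC
ASTL	GTAACCTAATTGCAGAACCGGCACCACCACCCCCTCTTAAATAGCAGCTGctccacctcc
SNAI1	CCACCACCCCCCCGGAGTACTTAAGGGAGTTGGCGGCGCTGCTGCATTCATTGCGCCGCG
ALG3	aagcggaacctaagtgtcgaaggttcgggtttccgggggtggtgggcccACACAAGCGGC
UNC5A	GCCCACCACCCCAAGCCCCTCCCTGGGGGAGCCTCAGGCATCGCCCAGAGGGATTCCCGG
APOM	acacacccaccaccccgcggctccgcccccgacttccccacggaccgtcACTTCCGGTCT
TMEM139	acctacccgctccggcccttcccaccaccccccaccccatctactttctACAGTCTGTGG
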