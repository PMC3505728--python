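gene	fold_change	p_value	mre
BIK	-10.38%	0.0187	ATTCCGAGGAGCAGGAGTGCTC
CHRNA2	-6.54%	0.0482	CACTGGCTGGAGAGCAACGTGGATGCC
DISC1	-8.55%	0.0370	TCTAGTTCATTAAAAGTGAATGTT
ENKUR_1	-9.10%	0.0014	CCTTAATGAATAAAGTAATGGATCGTA
ENKUR_2	-8.33%	0.0010	CATCGCTAAGTAAGCAACTTAAGTTGCTT
FGA_1	-20.19%	0.0225	TCCACTAGACGTTGTAATGCACACT
FGA_2	-9.24%	0.0025	TTTGATCCAGCAAAGAATGGATGGATC
GPR78	-17.25%	0.0032	GACGCCCAAAGCAGGATGTGTCTT
KCNMB2	-60.23%	<0.0001	CATTACCTGTGAGCTGACTGAATGTT
MTMR1	-18.45%	0.0496	CCCCTGGCTGACTAGGACTGTT
MMP14	-16.68%	0.0490	CCCACCCAGCCCACCCATTGAAGTCT
NR6A1_1	-18.27%	0.0152	TTCACGACAGAGTTGAATGTAT
NR6A1_2	-14.68%	0.0180	ACCAGCTGAGCAGAATGCCATGTT
SLC22A7	-9.38%	0.0392	CACCCTGCAGGGCAATGCATGTC
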