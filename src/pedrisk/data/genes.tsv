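gene	model	allele_freq	sensitivity	dominance_rank
BRCA1	bc	0.0006394	0.89	1
BRCA2	bc	0.00102	0.96	2
PALB2	bc	0.00064	0.92	3
CHEK2	bc	0.00373	0.98	4
ATM	bc	0.0018	0.94	5
BARD1	bc	0.00043	0.89	6
RAD51C	bc	0.00035	0.78	7
RAD51D	bc	0.00035	0.86	8
BRCA1	eoc	0.0007947	0.89	1
BRCA2	eoc	0.002576	0.96	2
RAD51D	eoc	0.00035	0.86	3
RAD51C	eoc	0.00035	0.78	4
BRIP1	eoc	0.00071	0.95	5
PALB2	eoc	0.00064	0.92	6
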