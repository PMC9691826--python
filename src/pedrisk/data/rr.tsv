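gene	cancer	age_lo	age_hi	form	c	u	v
BRCA1	bc	0	19	const	1	0	0
BRCA1	bc	20	29	loglin	0	3.0146	0.02412
BRCA1	bc	30	39	loglin	0	6.0707	-0.07775
BRCA1	bc	40	49	loglin	0	4.2511	-0.03226
BRCA1	bc	50	79	loglin	0	4.2086	-0.03141
BRCA1	eoc	0	29	const	1	0	0
BRCA1	eoc	30	39	loglin	0	-3.55	0.1986
BRCA1	eoc	40	49	loglin	0	7.1776	-0.06959
BRCA1	eoc	50	79	loglin	0	4.5236	-0.01651
BRCA1	mbc	0	79	const	8	0	0
BRCA1	prostate	0	64	const	1.82	0	0
BRCA1	prostate	65	79	const	0.84	0	0
BRCA1	pancreas	0	64	const	3.10	0	0
BRCA1	pancreas	65	79	const	1.54	0	0
BRCA2	bc	0	19	const	1	0	0
BRCA2	bc	20	29	loglin	0	3.2153	-0.008815
BRCA2	bc	30	39	loglin	0	4.28945	-0.04462
BRCA2	bc	40	49	loglin	0	3.96865	-0.0366
BRCA2	bc	50	59	loglin	0	1.8169	0.006435
BRCA2	bc	60	69	loglin	0	-0.2606	0.04106
BRCA2	bc	70	79	const	13.0991	0	0
BRCA2	eoc	0	39	const	1	0	0
BRCA2	eoc	40	53	loglin	0	-9.708	0.2427
BRCA2	eoc	54	57	loglin	0	6.50334	-0.05751
BRCA2	eoc	58	69	loglin	0	11.3175	-0.140513
BRCA2	eoc	70	79	const	4.4	0	0
BRCA2	mbc	0	79	const	80	0	0
BRCA2	prostate	0	64	const	7.33	0	0
BRCA2	prostate	65	79	const	3.39	0	0
BRCA2	pancreas	0	64	const	5.54	0	0
BRCA2	pancreas	65	79	const	1.61	0	0
PALB2	bc	0	19	const	1	0	0
PALB2	bc	20	24	const	9.1	0	0
PALB2	bc	25	29	const	8.97	0	0
PALB2	bc	30	34	const	8.85	0	0
PALB2	bc	35	39	const	8.54	0	0
PALB2	bc	40	44	const	8.02	0	0
PALB2	bc	45	49	const	7.31	0	0
PALB2	bc	50	54	const	6.55	0	0
PALB2	bc	55	59	const	5.92	0	0
PALB2	bc	60	64	const	5.45	0	0
PALB2	bc	65	69	const	5.1	0	0
PALB2	bc	70	74	const	4.82	0	0
PALB2	bc	75	79	const	4.56	0	0
PALB2	eoc	0	29	const	1	0	0
PALB2	eoc	30	79	const	2.91	0	0
PALB2	mbc	0	29	const	1	0	0
PALB2	mbc	30	79	const	7.34	0	0
PALB2	pancreas	0	29	const	1	0	0
PALB2	pancreas	30	79	const	2.37	0	0
CHEK2	bc	0	19	const	1	0	0
CHEK2	bc	20	79	loglin	0	1.6053	-0.01483
ATM	bc	0	79	const	2.10	0	0
BARD1	bc	0	79	const	2.09	0	0
RAD51C	bc	0	79	const	1.97	0	0
RAD51C	eoc	0	29	const	1	0	0
RAD51C	eoc	30	59	loglin	0	-1.7974	0.07631
RAD51C	eoc	60	79	loglin	0	9.7592	-0.1163
RAD51D	bc	0	79	const	1.82	0	0
RAD51D	eoc	0	29	const	1	0	0
RAD51D	eoc	30	57	loglin	0	-2.88662	0.09656
RAD51D	eoc	58	79	loglin	0	5.99144	-0.05651
BRIP1	eoc	0	79	const	3.41	0	0
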