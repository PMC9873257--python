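3N cell type	Cell ID	# mlSEZt input cells	mlSEZt input types	# mlSEZt synapses	% Input from mlSEZt	Target regions
SLP191	420973599	7	mAL3A, mAL3B	64	6.6	AVLP, SCL, SIP, SLP
SLP132	359892669	6	mAL3A, mAL4	54	2.1	AVLP, LH, SCL, SIP, SLP
SMP389	575197482	8	mAL3A, mAL3B,mAL4	48	3.4	AVLP, PLP, SCL, SIP, SLP, SMP
SLP191	421313563	8	mAL3A, mAL3B, mAL4	47	5.0	AVLP, LH, SCL, SIP, SLP
aSP-g3B	421650982	5	mAL3A	46	12.9	AVLP, PLP, SCL, SIP, SLP, SMP, SMP(C)
LHAV4l1	360236724	4	mAL4	41	3.3	AVLP, LH, SCL, SIP, SLP
SLP179_b	420623873	5	mAL3B, mAL4	38	3.7	SCL, SIP, SLP
LHAV2f2_b	574710121	5	mAL3A, mAL3B, mAL4	38	7.9	AVLP, LH, SCL, SLP
LHAV2f2_a	604735525	4	mAL3B, mAL4	36	9.4	AVLP, LH, SCL, SLP
LHAV2f2_b	573346324	5	mAL3A, mAL4	35	5.5	AVLP, LH, SCL, SLP
aSP-g3A	329919036	5	mAL3A, mAL3B, mAL4	35	6.3	SIP, SLP, SMP(C), SMP
LHAV1e1	390271033	4	mAL3A, mAL3B, mAL4	35	2.2	AVLP, LH, SCL, SIP, SLP
SLP015_e	393340402	4	mAL3B, mAL4	33	6.0	SIP, SLP
SLP011	297519736	7	mAL3A, mAL4	33	2.2	LH, SCL, SIP, SLP
SLP179_b	391311186	5	mAL3B, mAL4	32	3.3	SIP, SLP
SLP015_c	359240144	5	mAL3B, mAL4	28	3.1	AVLP, SCL, SIP, SLP
aSP-g3B	485430336	5	mAL3A	27	9.2	AVLP, SCL, SIP, SLP, SMP
SLP187	578521941	2	mAL3B	27	11.8	SIP, SLP
SLP187	607820937	2	mAL3B	26	7.3	AVLP, SCL, SLP
SLP376	298254384	4	mAL3B, mAL4	25	0.6	SIP, SLP, SMP
SLP216	5813011119	7	mAL3A, mAL3B, mAL4	25	1.0	AOTU, AVLP, GOR, GOR(C), IB, ICL, LH, PLP, SCL, SIP, SLP, SMP, SMP(C)
SLP215	608534097	3	mAL3B, mAL4	24	1.1	AVLP, PLP, SCL, SLP, VES
SLP015_c	359926923	4	mAL3B, mAL4	23	5.4	SIP, SLP
SLP187	483711811	3	mAL3B	23	8.9	SLP
SLP259	5813040707	4	mAL3B, mAL4	23	1.7	AVLP, SCL, SIP, SLP, SMP
AVLP024	420965117	3	mAL3B	22	1.2	AVLP, LH, PVLP, SCL, SIP, SLP
LHCENT1	328861282	4	mAL4	22	0.2	AVLP, LH, MB, SCL, SIP, SLP, SMP
LHAV6a10	5813047255	3	mAL4	22	6.5	LH, SIP, SLP
SLP015_e	329206628	2	mAL4	21	3.2	SIP, SLP
SMP550	452689494	3	mAL3B, mAL4	21	0.4	AVLP, LH, PLP, SCL, SIP, SLP, SMP
SLP018	451663172	4	mAL3A, mAL3B, mAL4	20	3.1	AVLP, LH, SCL, SIP, SLP
SLP057	5813019955	4	mAL3B, mAL4	20	0.5	AVLP, LH, PLP, SCL, SIP, SLP
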