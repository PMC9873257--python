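4N cell type	Cell ID	# 3N input cells	3N input cell types	# synapses from 3Ns	% input from 3Ns	Target regions
SMP548	297580589	16	AVLP024, LHAV1e1, SLP015_c, SLP015_e, SLP057, SLP179_b, SLP191, SLP216, SMP389, SMP550, aSP-g3A, aSP-g3B	363	6.3	AVLP, LH, PLP, SCL, SIP, SLP, SMP
SLP279	360591860	8	LHAV1e1, LHCENT1, SLP015_e, SLP018, SLP179_b, SLP216, SMP550, aSP-g3A	354	8.4	SCL, SIP, SLP, SMP, SMP(C)
LHCENT4	517506265	4	LHAV4l1, LHCENT1, SLP057, SMP389	297	4.6	AVLP, LH,, MB, PLP, SCL, SIP, SLP, SMP, mALT
DM1_lPN	542634818	1	LHCENT1	247	2.4	AL, LH, MB, SCL, SLP, mALT
LHMB1	5813020988	2	LHCENT1, SLP057	238	3.5	CRE, LH, MB, SCL, SIP, SLP, SMP
SLP388	298258611	11	AVLP024, SLP015_e, SLP018, SLP179_b, SLP191, SLP216, SMP389, aSP-g3B	203	3.1	SCL, SIP, SLP, SMP, SMP(C)
SMP550	452689494	7	AVLP024, LHAV1e1, SLP018, SLP216, SMP389, aSP-g3B	201	4.2	AVLP, LH, PLP, SCL, SIP, SLP, SMP
oviIN	423101189	2	SMP389, SMP550	190	0.8	CAN, CRE, CRE(C), GOR, IB, LAL, SIP, SIP(C), SMP, SMP(C), SPS, VES
LHCENT9	330268940	10	AVLP024, LHAV1e1, LHCENT1, SLP132, SLP191, SMP389, aSP-g3A, aSP-g3B	177	1.4	AOTU, AVLP, LH, MB, SCL, SIP, SLP, SMP
SLP212	5812980529	14	AVLP024, SLP015_e, SLP018, SLP057, SLP132, SLP191, SLP216, SMP389, SMP550, aSP-g3A, aSP-g3B	145	6.7	SIP, SLP, SMP, SMP(C)
SMP108	298258513	3	SLP057, SMP389, SMP550	145	0.6	CRE, CRE(C), LAL, LH, MB, MB(C), SCL, SIP(C), SIP, SLP, SMP, SMP(C)
oviDNa	550655668	2	SLP216, SMP550	137	12.3	CRE, SCL, SIP, SLP, SMP, SMP(C), VES
MBON18	5813020828	1	LHCENT1	132	1.0	LH, MB, SCL, SIP, SLP
LHPD4c1	421641859	9	LHAV1e1, LHAV4l1, LHCENT1, SLP011, SLP018, SLP057, SLP132, SLP187	130	2.5	LH, SCL, SIP, SLP, SMP
SLP113	390589591	6	AVLP024, LHAV2f2_b, LHAV4l1, LHCENT1, SLP132	127	10.5	LH, SIP, SLP, SMP
LHPV10b1	604709727	2	LHCENT1, SLP057	125	2.8	CRE, LH, MB, PLP, PVLP, SCL, SIP, SLP, SMP
SMP156	673776769	3	SLP216, SMP389, SMP550	124	2.1	CRE, GOR(C), IB, ICL(C), ICL, LAL, MB, SMP, SMP(C), SPS, SPS(C)
SMP385	5813083780	2	SMP389, SMP550	124	2.0	CRE, CRE(C), LAL, LAL(C), SCL, SIP, SIP(C), SMP, SMP(C),
SLP440	328870472	13	LHAV1e1, SLP015_c, SLP015_e, SLP018, SLP057, SLP179_b, SLP191, SLP376, aSP-g3B	123	3.0	LH, SCL, SIP, SLP, SMP, SMP(C)
LHPV5e1	328611004	5	LHAV1e1, LHAV4l1, LHCENT1, SLP015_e, SLP132	123	1.1	CRE, CRE(C), LH, MB(C), SCL, SIP, SIP(C), SLP, SMP, SMP(C)
SMP029	604070433	3	SLP216, SMP389, SMP550	120	6.7	AVLP, LH, MB, PLP, SCL, SIP, SLP, SMP
SMP311	5813049378	2	SMP389, SMP550	117	7.5	AVLP, ICL, PLP, SCL, SIP, SLP, SMP
PPL201	328533761	6	LHAV1e1, LHCENT1, SLP011, SLP015_e, SLP057, SLP179_b	117	1.4	AVLP, CRE, LH, MB, PLP, POC, SCL, SIP, SLP, SMP, mALT
SMP109	5813009620	2	SMP389, SMP550	107	1.7	AOTU, CRE, CRE(C), LAL, LAL(C), MB, SIP, SMP, VES
SMP029	541347811	4	SLP215, SLP216, SMP389, SMP550	106	5.8	AVLP, MB, PLP, SCL, SIP, SLP, SMP
SMP503	361312808	12	AVLP024, LHCENT1, SLP011, SLP015_e, SLP018, SLP132, SLP187, SLP215, SMP389, SMP550, aSP-g3B	102	1.5	AVLP, CRE, LH, MB, PLP, SCL, SIP, SIP(C), SLP, SMP, SMP(C)
SLP113	421271305	8	LHAV2f2_a, LHAV2f2_b, LHAV4l1, LHCENT1, SLP132, SLP187	102	10.0	LH, SIP, SLP, SMP, SMP(C)
MBON18	457196444	1	LHCENT1	97	3.6	LH, MB(C), SCL, SIP, SIP(C), SLP
SLP149	5813009312	9	LHAV1e1, LHAV4l1, LHCENT1, SLP015_c, SLP018, SLP057, SLP179_b, SLP376	97	4.3	SIP, SLP, SMP
SLP441	5813078542	13	LHAV1e1, LHCENT1, SLP011, SLP015_c, SLP015_e, SLP057, SLP179_b, SLP191, SLP259, SLP376, aSP-g3B	96	3.3	AVLP, SCL, SIP, SLP, SMP
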