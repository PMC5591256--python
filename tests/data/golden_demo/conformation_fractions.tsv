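chain	residue	n_frames	base	chemistry	syn	low_anti	mid_anti	high_anti	other	north	south
W	3	30	G	DNA	0.0000	0.0333	0.7333	0.2333	0.0000	0.0000	1.0000
W	4	30	G	DNA	0.0000	0.0000	0.5667	0.4000	0.0333	0.4000	0.6000
W	5	30	A	DNA	0.0000	0.0333	0.5333	0.4333	0.0000	1.0000	0.0000
W	6	30	A	DNA	0.0000	0.0333	0.6000	0.3667	0.0000	1.0000	0.0000
W	7	30	A	DNA	0.0000	0.0000	0.6000	0.4000	0.0000	0.0000	1.0000
W	8	30	A	DNA	0.0000	0.0000	0.5667	0.4000	0.0333	0.0000	1.0000
W	9	30	G	DNA	0.0000	0.0333	0.6667	0.3000	0.0000	0.0000	1.0000
W	10	30	A	DNA	0.0000	0.0000	0.6000	0.3667	0.0333	0.0000	1.0000
W	11	30	A	DNA	0.0000	0.0000	0.7000	0.3000	0.0000	0.0000	1.0000
W	12	30	A	DNA	0.0000	0.0000	0.7000	0.3000	0.0000	0.0000	1.0000
W	13	30	A	DNA	0.0000	0.0333	0.6667	0.2667	0.0333	1.0000	0.0000
W	14	30	A	DNA	0.0000	0.0000	0.6333	0.3667	0.0000	0.0000	1.0000
W	15	30	A	DNA	0.0000	0.0667	0.7000	0.2333	0.0000	0.0000	1.0000
W	16	30	G	DNA	0.0000	0.0333	0.6333	0.3333	0.0000	0.0000	1.0000
W	17	30	A	DNA	0.0000	0.0000	0.7333	0.2667	0.0000	1.0000	0.0000
C	3	30	T	DNA	0.0000	0.0000	0.7000	0.3000	0.0000	0.0000	1.0000
C	4	30	C	DNA	0.0000	0.0000	0.8333	0.1667	0.0000	0.6667	0.3333
C	5	30	T	DNA	0.0000	0.0000	0.7000	0.3000	0.0000	0.0000	1.0000
C	6	30	T	DNA	0.0000	0.0000	0.7333	0.2667	0.0000	0.9000	0.1000
C	7	30	T	DNA	0.0000	0.0000	0.6333	0.3667	0.0000	0.0000	1.0000
C	8	30	T	DNA	0.0000	0.0000	0.9333	0.0667	0.0000	0.0000	1.0000
C	9	30	T	DNA	0.0000	0.0000	0.7000	0.3000	0.0000	0.0000	1.0000
C	10	30	T	DNA	0.0000	0.0000	0.7667	0.2333	0.0000	0.8333	0.1667
C	11	30	C	DNA	0.0000	0.0000	0.6667	0.3333	0.0000	0.2333	0.7667
C	12	30	T	DNA	0.0000	0.0000	0.5000	0.5000	0.0000	0.4333	0.5667
C	13	30	T	DNA	0.0000	0.0000	0.8333	0.1667	0.0000	0.2333	0.7667
C	14	30	T	DNA	0.0000	0.0000	0.8000	0.2000	0.0000	0.0000	1.0000
C	15	30	T	DNA	0.0000	0.0000	0.6667	0.3000	0.0333	0.2667	0.7333
C	16	30	C	DNA	0.0000	0.0333	0.5667	0.4000	0.0000	0.0000	1.0000
C	17	30	C	DNA	0.0000	0.0000	0.7667	0.2333	0.0000	1.0000	0.0000
T	3	30	T	DNA	0.0000	0.7667	0.1333	0.0333	0.0667	1.0000	0.0000
T	4	30	T	LNA	0.0000	0.8000	0.2000	0.0000	0.0000	1.0000	0.0000
T	5	30	T	DNA	0.0000	0.7667	0.1667	0.0000	0.0667	0.2333	0.7667
T	6	30	T	LNA	0.0000	0.8333	0.1667	0.0000	0.0000	1.0000	0.0000
T	7	30	C	DNA	0.0000	0.8000	0.2000	0.0000	0.0000	0.8333	0.1667
T	8	30	T	LNA	0.0000	0.9000	0.0667	0.0000	0.0333	1.0000	0.0000
T	9	30	T	DNA	0.0000	0.8000	0.2000	0.0000	0.0000	0.0000	1.0000
T	10	30	T	LNA	0.0000	0.9667	0.0333	0.0000	0.0000	1.0000	0.0000
T	11	30	T	DNA	0.0000	0.8333	0.1667	0.0000	0.0000	0.0000	1.0000
T	12	30	T	LNA	0.0000	0.9000	0.0333	0.0000	0.0667	1.0000	0.0000
T	13	30	T	DNA	0.0000	0.8333	0.1667	0.0000	0.0000	0.0000	1.0000
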