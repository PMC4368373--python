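family	member	sequence	length	mir_length	mn	mean_count
ath-miR156	a	tgacagaagagagtgagcac	20	21	0	2247.09
ath-miR156	g	ggacagaagagagtgagcac	20	20	0	13.01
vvi-miR156	h	ttgacagaagagagagagcat	21	20	1	5.73
ath-miR156	i	tgacagaagagagagagca	19	21	0	1.92
ath-miR156	j	tgacagaagagagagagcac	20	21	0	4.43
ath-miR159	a	tttggattgaagggagct	18	21	0	1.28
ath-miR160	a	tgcctggctccctgtatgcca	21	21	0	3125.22
ath-miR166	a	tcggaccaggcttcattcccc	21	21	0	309522.05
osa-miR171	i-5p	aggtattggcgcgcctcaatt	21	21	1	0.97
ath-miR319	a	cttggactgaagggagctcccttt	24	21	0	8.34
ath-miR390	a	aagctcaggagggatagcg	19	21	0	235.63
bdi-miR395	d	tccaagtgtttcgggtactctagg	24	21	2	1.77
ath-miR396	b	ttccacagctttcttgaactt	21	21	0	13.79
ath-miR408		atgcactgcctcttccctggc	21	21	0	388.61
osa-miR535	-5p	tgacaacgagagagagcacgc	21	21	0	4374.19
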