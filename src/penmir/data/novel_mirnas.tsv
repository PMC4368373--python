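name	sequence	length	mean_count	note
pen-miR8156a	tctcccacacatcgtctagga	21	19879060.23
pen-miR8156b	tctcccacacatcgtctaggc	21	58077.70
pen-miR8156c	tctgccacacatcgtctagga	21	22901.49
pen-miR8156d	tcgcccacacatcgtctagga	21	9325.45
pen-miR8157	tttcccagacatcgtcgatga	21	2780091.24
pen-miR8158	tgaaggacgcattctgctcga	21	320926.69
pen-miR8159a	ttaccttgaagagtctggaag	21	298119.06
pen-miR8159b	ttaccttgaagagtctggaa	20	116532.20
pen-miR8160	tccctaaagactcgggcaata	21	127680.15
pen-miR8161	ttcgagcagagaggtggagcc	21	424963.43
pen-miR8162-5p	tttgtaagaattggaaccgga	21	75985.52
pen-miR8162-3p	tggatccatttcttacagacg	21	65120.30
pen-miR8163	ccccgtggaagaaaacaatctca	23	191569.82
pen-miR8164	caatttgtggcaaacttcccc	21	103523.36
pen-miR8165	ttgctagagaggactttcctt	21	59900.20
pen-miR8166	ttgctttgggagacatcagttc	22	245117.49
pen-miR8167	ccatgcctactatacccaatc	21	31174.82
pen-miR8168	ggggacgtagctcaatcgg	19	228305.93
pen-miR8169	tgcgataagaagggttgagct	21	52738.45
pen-miR8170	tgcttcacagaggagatgcat	21	35621.35
pen-miR8171	caatagaagcatgggactgag	21	30129.15
pen-miR8172.1	tcggacgttatcacgccttgg	21	14799.01
pen-miR8172.2	tctaagtcgggaagccaaggc	21	57485.07
pen-miR8173	ccagtaggagatgtgatcgta	21	132404.08
pen-miR8175	ccatgcctgctatatccaatc	21	17454.77
pen-miR8176	tctgtgtttcaggacctcaaa	21	11953.24
pen-miR8177	tctgatggactgcagggcatg	21	24212.20
pen-miR8178	tggggtcctataagtcatcaa	21	26231.57
pen-miR8179	tgggatacagtaggcataact	21	65510.02
pen-miR8180	tacagacttgcactcgtcgtc	21	51215.78
pen-miR8181	ggcccgtgcggtcggatggacc	22	5743.34
pen-miR8182	tctctcagtctggcacttaca	21	89872.87
pen-miR8183.1	gaaccgggactggaaggaggc	21	4846.39
pen-miR8183.2	gggactggaaggaggctgaga	21	111970.03	algal_homolog
pen-miR8184	tggaggaagagacattgtgac	21	32.62
pen-miR8185	taaagatgatgggttttgttg	21	21593.70	algal_homolog
pen-miR8186	cttgcagcaagcagatcccag	21	29270.63
pen-miR8187	acaaggtatgggaggtatggaatg	24	7878.44
pen-miR8188	agaaacgctgcaacggaacca	21	23546.63
pen-miR8189	aggaggatagtacagggttgt	21	2151.33
pen-miR8190	gagggttgcagagtggttttgg	22	9799.49
pen-miR408-5p	ctagggtgaggcatggcatg	20	94669.44	conserved_star
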