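name	pen_sequence	algal_sequence	algal_label
pen-miR8183.2	gggactggaaggaggctgaga	acctggaaggaggctgag	cre_sRNA
pen-miR8185	taaagatgatgggttttgttg	aatgatgatgggttttgt	cre_sRNA
pen-miR1144	gtagggtggaggcaggca	tgggtagtgtggcggcaggcag	cre-miR1144b
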