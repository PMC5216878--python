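# Transcription of the published per-region diversity summary for the
# Mesoamerican wild (MW) and domesticated (MD) panels.
# n_loci: loci contributing; N/H/Hd/pi_e3/theta_e3 are across-locus means
# (pi and theta printed x 1e3); V/eta/S/Pi/Syn/Nonsyn are across-locus sums.
# "/" marks structurally absent cells.
region	statistic	MW	MD
whole	n_loci	49	49
whole	N	18.6	19.7
whole	V	411	218
whole	eta	418	219
whole	S	123	67
whole	Pi	288	151
whole	Syn	/	/
whole	Nonsyn	/	/
whole	H	4.8	2.4
whole	Hd	0.58	0.27
whole	pi_e3	5.39	2.70
whole	theta_e3	5.26	2.64
coding	n_loci	42	42
coding	N	18.7	19.8
coding	V	133	78
coding	eta	134	78
coding	S	52	28
coding	Pi	81	50
coding	Syn	82	45
coding	Nonsyn	50	32
coding	H	3.1	2.0
coding	Hd	0.38	0.20
coding	pi_e3	3.29	1.69
coding	theta_e3	3.09	1.77
noncoding	n_loci	37	37
noncoding	N	18.7	19.8
noncoding	V	242	114
noncoding	eta	248	115
noncoding	S	66	36
noncoding	Pi	176	78
noncoding	Syn	/	/
noncoding	Nonsyn	/	/
noncoding	H	4.0	1.9
noncoding	Hd	0.48	0.20
noncoding	pi_e3	7.66	3.45
noncoding	theta_e3	7.47	3.24
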