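# Published loss-of-diversity statistics, MD vs MW: mean-based (L_pi,
# L_theta) and per-locus-averaged (L_pi1, L_theta1), per region.
region	L_pi	L_pi1	L_theta	L_theta1
whole	0.50	0.57	0.50	0.53
coding	0.49	0.55	0.43	0.42
noncoding	0.55	0.57	0.57	0.60
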