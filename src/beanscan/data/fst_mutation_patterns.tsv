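# Transcription of the published per-locus Hudson-FST and shared/private
# mutation table for the MW/MD contrast.  Sentinels: "na" = locus (region)
# monomorphic in all Mesoamerican accessions, FST undefined; "/" = region
# structurally absent.  sig_* is the star level of the permutation test
# (0 = n.s., 1..3 increasing significance; empty when FST is a sentinel).
locus	fst_whole	sig_whole	sm_whole	pmw_whole	pmd_whole	fst_coding	sig_coding	sm_coding	pmw_coding	pmd_coding	fst_noncoding	sig_noncoding	sm_noncoding	pmw_noncoding	pmd_noncoding
AN-Pv1	0.12	1	0	6	0	0.06	1	0	5	0	0.22	1	0	1	0
AN-Pv2	0.01	0	4	1	0	0.02	0	1	0	0	0.00	0	3	1	0
AN-Pv3	0.06	1	1	6	0	0.08	0	1	3	0	0.00	0	0	3	0
AN-Pv4	0.16	1	1	2	0	na		na	na	na	0.16	1	1	2	0
AN-Pv5	0.04	0	0	3	0	na		na	na	na	0.04	0	0	3	0
AN-Pv8	0.21	3	2	4	1	0.21	2	2	4	1	/		/	/	/
AN-Pv9	na		na	na	na	na		na	na	na	na		na	na	na
AN-Pv10	0.02	0	5	3	0	0.01	0	4	0	0	0.05	0	1	3	0
AN-Pv16	0.33	3	0	7	0	/		/	/	/	0.33	2	0	7	0
AN-Pv17	0.11	0	0	1	0	na		na	na	na	0.11	0	0	1	0
AN-Pv18	0.01	0	0	9	1	0.01	0	0	9	1	/		/	/	/
AN-Pv22	0.46	3	4	7	0	0.44	3	3	4	0	0.50	3	1	3	0
AN-Pv26.1	0.65	3	9	7	0	0.57	3	3	4	0	0.68	3	6	3	0
AN-Pv28	0.01	1	5	1	0	0.01	0	1	0	0	0.01	1	4	1	0
AN-Pv29	0.09	0	3	1	1	0.11	0	1	0	0	0.08	0	2	1	1
AN-Pv30	0.19	3	3	1	0	0.19	2	3	1	0	/		/	/	/
AN-Pv32	na		na	na	na	na		na	na	na	na		na	na	na
AN-Pv33	0.37	3	0	4	0	0.37	3	0	4	0	/		/	/	/
AN-Pv35	0.06	0	0	2	0	na		na	na	na	0.06	0	0	2	0
AN-Pv41	0.00	0	1	2	0	/		/	/	/	0.00	0	1	2	0
AN-Pv42	0.02	0	3	2	0	/		/	/	/	0.02	0	3	2	0
AN-Pv44	-0.01	0	3	0	1	-0.01	0	3	0	1	na		na	na	na
AN-Pv46	0.25	2	3	1	0	0.25	1	3	1	0	na		na	na	na
AN-Pv47	0.23	1	8	3	0	0.18	1	4	2	0	0.28	1	4	1	0
AN-Pv48	0.01	0	17	2	2	/		/	/	/	/		/	/	/
AN-Pv51	0.08	3	12	7	0	0.08	3	5	3	0	0.07	1	7	4	0
AN-Pv54	0.03	0	5	1	2	0.03	1	5	1	2	/		/	/	/
AN-Pv55	na		na	na	na	na		na	na	na	na		na	na	na
AN-Pv57	-0.03	0	11	2	0	-0.04	0	3	2	0	-0.03	0	8	0	0
AN-Pv63	0.19	3	5	3	0	0.19	3	5	3	0	/		/	/	/
AN-Pv64	0.25	3	0	8	0	na		na	na	na	0.25	3	0	8	0
AN-Pv66	0.02	1	0	4	0	0.02	0	0	4	0	/		/	/	/
AN-Pv68	-0.03	0	8	9	1	-0.02	0	4	5	0	-0.03	0	4	4	1
AN-Pv69	0.59	3	0	2	0	0.22	1	0	1	0	0.72	3	0	1	0
gssE18	0.20	3	4	3	1	0.19	1	2	0	0	0.21	3	2	3	1
gssE19	0.08	0	0	2	0	/		/	/	/	/		/	/	/
gssE20	na		na	na	na	na		na	na	na	na		na	na	na
gssE28	0.00	0	4	6	0	/		/	/	/	/		/	/	/
AN-PvCO	0.05	0	11	5	1	0.05	0	6	1	1	0.05	0	5	4	0
AN-TGA	0.23	3	3	11	0	0.00	0	0	1	0	0.23	3	3	10	0
AN-DNAJ	0.41	3	3	3	1	0.41	3	3	3	1	/		/	/	/
g510	0.26	3	8	2	0	0.29	2	7	1	0	-0.04	0	1	1	0
g523	0.41	3	2	0	1	0.31	2	1	0	1	0.42	2	1	0	0
Leg044	-0.02	0	10	12	0	na		na	na	na	-0.02	0	10	12	0
Leg100	0.08	3	22	18	1	na		na	na	na	0.08	3	22	18	1
Leg133	0.35	3	1	12	0	0.06	0	0	1	0	0.36	3	1	11	0
Leg223	0.33	3	0	6	0	na		na	na	na	0.33	3	0	6	0
Leg443	0.00	0	3	2	0	/		/	/	/	/		/	/	/
PvSHP1	0.22	3	21	20	0	0.00	0	0	1	0	0.22	3	21	19	0
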