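sample	kit	depth	breadth	n_variants
Sample 1	LSK109	0.36	27	69700
Sample 2	LSK109	0.51	36	139412
Sample 3	LSK109	0.41	29	84872
Sample 5	LSK109	0.54	37	143414
Sample 6	LSK109	0.54	37	151828
Sample 8	LSK109	0.61	41	169916
Sample 9	LSK109	0.45	32	108916
Sample 10	LSK109	1.04	58	495019
Sample 11	LSK109	0.88	53	361627
Sample 12	LSK109	1.07	60	490223
Sample 13	Q20	0.41	29	115022
Sample 14	Q20	0.30	22	65840
Sample 15	Q20	0.38	27	93316
Sample 16	Q20	0.31	22	67232
Sample 17	Q20	0.33	24	76340
Sample 18	Q20	0.36	26	91323
Sample 19	Q20	0.86	49	419787
Sample 20	Q20	0.47	32	145412
Sample 21	Q20	0.74	44	321066
Sample 22	Q20	0.31	22	74607
Sample 23	Q20	0.49	30	140729
Sample 24	Q20	0.38	26	94729
Sample 25	LSK114	2.43	82	1924878
Sample 26	LSK114	2.10	76	1533807
Sample 27	LSK114	1.87	73	1311229
Sample 28	LSK114	1.92	73	1375101
Sample 29	LSK114	1.78	71	1246664
Sample 30	LSK114	2.93	87	2420455
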