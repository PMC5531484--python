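patient_id	n_class3	note
42	5
43	7	carrier of CBS p.I278T
44	3
45	9
46	6
47	2
48	11
49	8	carrier of CBS p.I278T
50	4
51	6	myelodysplasia diagnosis emerged; consistent with absence of class 4/5 variants
52	7
53	1
54	10	carrier of CBS p.I278T
55	5
56	13
57	3
58	6	VIP2 re-run internal control; 3 extra class-3 calls in VIP2 due to improved coverage
59	8
60	2
61	7
62	9	carrier of CBS p.I278T
63	4
64	16
65	6	VIP2 re-run internal control; 3 extra class-3 calls in VIP2 due to improved coverage
66	5
67	12
68	3
69	7
70	6
71	8	carrier of CBS p.I278T; Schnitzler syndrome diagnosis emerged
72	4
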