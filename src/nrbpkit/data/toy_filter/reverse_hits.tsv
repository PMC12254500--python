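# reverse search: candidate (query) vs reference proteome; accepted reference: REF1
C01	REF1	62.00	450	168	2	1	450	40	489	1e-58	200.0
C01	OTHER_KIN	35.00	420	260	4	10	430	15	430	1e-25	150.0
C02	REF1	40.00	450	265	3	1	450	40	489	1e-22	200.0
C02	OTHER_KIN	33.00	410	262	4	12	420	20	428	1e-12	90.0
C03	REF1	48.00	450	230	3	1	450	40	489	1e-30	200.0
C03	OTHER_KIN	34.00	400	255	4	15	415	25	424	1e-15	110.0
C04	OTHER_KIN	61.00	455	172	2	1	455	5	460	1e-55	220.0
C04	REF1	44.00	430	235	4	10	440	40	465	1e-28	150.0
C05	REF1	50.00	445	215	3	1	445	40	484	1e-45	180.0
C05	OTHER_KIN	50.00	445	216	3	1	445	8	450	1e-45	180.0
C06	REF1	55.00	395	172	2	1	395	60	455	1e-38	200.0
C06	OTHER_KIN	33.00	380	248	4	10	390	22	400	1e-14	105.0
C07	REF1	54.00	392	178	2	1	392	1	392	1e-38	200.0
C07	OTHER_KIN	32.00	370	245	4	12	382	30	398	1e-13	100.0
C08	REF1	55.00	440	190	3	1	440	5	444	1e-39	200.0
C08	OTHER_KIN	34.00	400	250	4	20	420	18	416	1e-16	115.0
C09	REF1	57.00	410	170	2	1	410	84	494	1e-39	200.0
C09	OTHER_KIN	35.00	390	242	4	15	405	28	416	1e-17	120.0
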