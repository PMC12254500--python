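# forward search: candidate (query) vs reference REF1 (subject, 500 residues)
C01	REF1	62.00	457	170	3	1	457	44	500	1e-60	220.0
C02	REF1	40.00	457	270	3	1	457	44	500	1e-20	80.0
C03	REF1	48.00	457	230	3	1	457	44	500	1e-28	120.0
C04	REF1	60.00	457	175	3	1	457	44	500	1e-50	200.0
C05	REF1	58.00	457	185	3	1	457	44	500	1e-50	195.0
C06	REF1	55.00	400	175	2	1	400	61	460	1e-40	160.0
C07	REF1	54.00	399	180	2	1	399	1	399	1e-40	158.0
C08	REF1	56.00	250	105	1	1	250	1	250	1e-40	150.0
C08	REF1	52.00	251	118	1	240	490	200	450	1e-35	140.0
C09	REF1	57.00	416	172	2	1	416	85	500	1e-40	165.0
C10	REF1	59.00	457	180	3	1	457	44	500	1e-40	170.0
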