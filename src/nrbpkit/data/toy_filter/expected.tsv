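# Documented expectations for the toy filter fixture.
# Chain: E-value <= 1e-28 (inclusive); reciprocal top hit in {REF1};
# coverage of REF1 (500 aa) >= 0.80 with HSP pooling; folded region 44:480
# with <= 40 uncovered residues.
# candidate	pass_evalue	pass_reciprocal	pass_coverage	pass_folded_region	accepted	note
C01	True	True	True	True	True	clean full-length hit
C02	False	True	True	True	False	E-value 1e-20 above cutoff
C03	True	True	True	True	True	E-value exactly at the inclusive cutoff
C04	True	False	True	True	False	reverse top hit is an unrelated kinase
C05	True	True	True	True	True	reverse tie at top bit score includes REF1
C06	True	True	True	True	True	coverage exactly 0.80; folded 37 uncovered
C07	True	True	False	False	False	coverage 399/500 just below threshold
C08	True	True	True	True	True	two HSPs pool to union 450/500; folded 30 uncovered
C09	True	True	True	False	False	folded region 41 residues uncovered (tolerance 40)
C10	True	False	True	True	False	no reverse hits at all
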