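# Ambiguous initial-query terms removed before embedding-based expansion.
# These short or polysemous synonyms attract high-cosine neighbours that are
# unrelated to the experimental method, so they are dropped from the initial
# query of the listed method. Format: MI id <TAB> term.
MI:0016	cd
MI:0018	2h
MI:0053	fps
MI:0055	ret
MI:0099	spa
MI:0104	sly
MI:0112	myth
MI:0114	x-ray
MI:0226	ice
MI:0419	gtpase
MI:0428	microscopy
MI:0437	trihybrid
MI:0676	tap
MI:0728	kiss
MI:0825	x-ray
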