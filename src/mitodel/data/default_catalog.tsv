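id	b5	b3	flank5	flank3	aux_queries
6335-13999	6335	13999	10	10
7816-14807	7816	14807	8	10	ATCCTAGT;GAAACTTCGG
8471-13449	8471	13449	15	15
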