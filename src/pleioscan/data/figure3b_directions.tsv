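rsid	gene	stated_allele	cancer_direction	expression_direction	risk_allele_expression
rs2070721	IRF1	G	decrease	decrease	increase
rs10230978	IKZF1	G	decrease	increase	decrease
rs3740688	SPI1	T	increase	increase	increase
rs3184504	SH2B3	C	increase	decrease	decrease
rs4788115	LAT	A	decrease	decrease	increase
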